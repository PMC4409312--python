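"""Regeneration of the study's model-derived figure panels.

Each function rebuilds the curves behind one main figure of the study —
steady-state I-V and resistance profiles, spike trajectories, f-V curves,
fluctuation-modulated f-I and spike-probability curves, phase-plane and
interval-probability analyses, and the noise-scaling comparison — and
writes CSV curves, fit JSONs and a summary PNG into a directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import (ELIFParams, PassiveLIFParams, HHParams,
                     holding_current, elif_rheobase)
from .noise import calibrate_noise_coefficient
from .protocols import (ProtocolConfig, fi_protocol,
                        spike_probability_protocol, phase_plane_curve)
from .analysis import fit_boltzmann
from .io import write_curve, write_json
from . import studies

ELIF_SET = {"elif2": ELIFParams(Delta_T=2.0),
            "elif5": ELIFParams(Delta_T=5.0),
            "elif15": ELIFParams(Delta_T=15.0)}


def _mkdir(outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def fig3(outdir, seed: int = 0) -> None:
    """I-V curves, resistance profiles, trajectories and f-V curves for
    the eLIF family (spike slope factor 2/5/15 mV) and the passive model."""
    outdir = _mkdir(outdir)
    models = dict(ELIF_SET, passive=PassiveLIFParams())
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    Vg = np.arange(-85.0, -56.0, 0.5)
    for name, p in models.items():
        iv = -p.rhs_current(Vg)  # steady-state injected current per voltage
        np.savetxt(outdir / f"iv_{name}.csv",
                   np.column_stack([Vg, iv]), delimiter=",",
                   header="V_mV,I_pA", comments="")
        axes[0, 0].plot(Vg, iv, label=name)
        rp = studies.resistance_profile(p)
        write_curve(rp, outdir / f"resistance_{name}.csv")
        axes[0, 1].plot(rp.x, rp.y, label=name)
        ts = studies.trajectory_study(p, seed=seed)
        np.savetxt(outdir / f"first_spike_{name}.csv",
                   np.column_stack([ts["first_spike"].t,
                                    ts["first_spike"].V_mean]),
                   delimiter=",", header="t_ms,V_mV", comments="")
        axes[1, 0].plot(ts["first_spike"].t, ts["first_spike"].V_mean,
                        label=name)
        fv = studies.fv_study(p, seed=seed)
        write_curve(fv["curve"], outdir / f"fv_{name}.csv")
        if fv["fit"] is not None:
            write_json(fv["fit"], outdir / f"fv_fit_{name}.json")
        axes[1, 1].plot(fv["curve"].x, fv["curve"].y, "o-", ms=3,
                        label=name)
    axes[0, 0].set(xlabel="V (mV)", ylabel="I (pA)", title="I-V")
    axes[0, 1].set(xlabel="V (mV)", ylabel="R (MΩ)",
                   title="input resistance")
    axes[1, 0].set(xlabel="t (ms)", ylabel="V (mV)",
                   title="first-spike trajectory (50 ms latency)")
    axes[1, 1].set(xlabel="mean V (mV)", ylabel="f (spikes/s)",
                   title="f-V")
    for ax in axes.flat:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "fig3.png", dpi=150)
    plt.close(fig)


def _fi_pair(params, coeff, seed, grid=25.0, n_above=12, repeats=20):
    """Deterministic and noisy f-I curves on a shared amplitude ladder."""
    rheo = elif_rheobase(params) - holding_current(params, -75.0)
    amps = np.arange(0.0, rheo + n_above * grid, grid)
    det = fi_protocol(params, ProtocolConfig(step_amplitudes=amps,
                                             step_duration=1000.0,
                                             seed_base=seed))
    noisy = fi_protocol(params, ProtocolConfig(
        step_amplitudes=amps, step_duration=1000.0, repeats=repeats,
        noise_coefficient=coeff, seed_base=seed + 1))
    return amps, det, noisy


def fig4(outdir, seed: int = 0) -> None:
    """Fluctuation modulation of f-I and spike-probability curves for the
    eLIF with spike slope factor 15 vs 2 mV, baseline and +15 nS shunt."""
    outdir = _mkdir(outdir)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    summary = {}
    for col, DT in enumerate((15.0, 2.0)):
        base = ELIFParams(Delta_T=DT)
        coeff = calibrate_noise_coefficient(base, seed=seed)
        for shunt, color in ((0.0, "k"), (15.0, "0.6")):
            p = ELIFParams(Delta_T=DT, g_shunt=shunt)
            label = f"DT{DT:g}_gsh{shunt:g}"
            amps, det, noisy = _fi_pair(p, coeff, seed)
            write_curve(det, outdir / f"fi_det_{label}.csv")
            write_curve(noisy, outdir / f"fi_noise_{label}.csv")
            axes[0, col].plot(amps, det.y, "--", color=color)
            axes[0, col].plot(amps, noisy.y, "-", color=color,
                              label=label)
            st = studies.low_region_delta_study(p, coeff, seed=seed)
            summary[label] = {"low_delta": st["delta"],
                              "rheobase_amp": st["rheobase_amp"]}
            # spike-probability pair
            trans = st["rheobase_amp"]
            pa = np.arange(trans - 120.0, trans + 90.0, 10.0)
            pn = spike_probability_protocol(p, ProtocolConfig(
                step_amplitudes=pa, step_duration=100.0, repeats=20,
                noise_coefficient=coeff, seed_base=seed + 2))
            write_curve(pn, outdir / f"pi_noise_{label}.csv")
            bfit = fit_boltzmann(pn.x, pn.y)
            summary[label]["boltzmann_k"] = bfit.k
            summary[label]["P02"] = bfit.P02_current
            axes[1, col].plot(pn.x, pn.y, "o-", ms=3, color=color,
                              label=label)
        axes[0, col].set(title=f"f-I, Δ_T = {DT:g} mV", xlabel="I (pA)",
                         ylabel="f (spikes/s)")
        axes[1, col].set(title=f"P(spike), Δ_T = {DT:g} mV",
                         xlabel="I (pA)", ylabel="P")
        axes[0, col].legend(fontsize=7)
    write_json(summary, outdir / "fig4_metrics.json")
    fig.tight_layout()
    fig.savefig(outdir / "fig4.png", dpi=150)
    plt.close(fig)


def fig5(outdir, seed: int = 0) -> None:
    """Gain compensation by the reset voltage: deterministic gain vs V_r,
    and fluctuation smoothing of spike-probability curves across the
    spike-slope-factor ladder."""
    outdir = _mkdir(outdir)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    sweeps = {}
    for DT in (2.0, 15.0):
        rows = studies.vr_gain_sweep(DT, np.arange(-80.0, -59.9, 2.5),
                                     seed=seed)
        sweeps[f"DT{DT:g}"] = rows
        axes[0].plot([r["V_r"] for r in rows], [r["gain"] for r in rows],
                     "o-", label=f"Δ_T = {DT:g}")
    write_json(sweeps, outdir / "vr_gain_sweep.json")
    shifts = {}
    for DT in (1.0, 2.0, 5.0, 10.0, 15.0):
        p = ELIFParams(Delta_T=DT)
        coeff = calibrate_noise_coefficient(p, seed=seed)
        from .protocols import step_transition_amplitude
        trans = step_transition_amplitude(p, 100.0)
        pa = np.arange(trans - 120.0, trans + 90.0, 10.0)
        pn = spike_probability_protocol(p, ProtocolConfig(
            step_amplitudes=pa, step_duration=100.0, repeats=20,
            noise_coefficient=coeff, seed_base=seed + 3))
        bfit = fit_boltzmann(pn.x, pn.y)
        shifts[f"DT{DT:g}"] = {"k": bfit.k,
                               "p02_shift": trans - bfit.P02_current}
        axes[1].plot(DT, bfit.k, "ks")
    write_json(shifts, outdir / "probability_metrics.json")
    axes[0].set(xlabel="V_r (mV)", ylabel="gain (spikes/pA s)")
    axes[0].legend(fontsize=8)
    axes[1].set(xlabel="Δ_T (mV)", ylabel="Boltzmann k (pA)")
    fig.tight_layout()
    fig.savefig(outdir / "fig5.png", dpi=150)
    plt.close(fig)


def fig6(outdir, seed: int = 0) -> None:
    """Conductance-based model: persistent-Na+ levels (150/75/0 nS) set
    sub-threshold resistance and the degree of fluctuation modulation."""
    outdir = _mkdir(outdir)
    from .protocols import step_transition_amplitude
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    metrics = {}
    for gnap, color in ((150.0, "r"), (75.0, "k"), (0.0, "c")):
        p = HHParams(g_Nap=gnap)
        label = f"gNap{gnap:g}"
        rp = studies.resistance_profile(p)
        write_curve(rp, outdir / f"resistance_{label}.csv")
        axes[0].plot(rp.x, rp.y, color=color, label=label)
        coeff = calibrate_noise_coefficient(p, seed=seed)
        trans = step_transition_amplitude(p, 1000.0, min_spikes=4)
        amps = np.arange(max(trans - 100.0, 0.0), trans + 300.0, 25.0)
        det = fi_protocol(p, ProtocolConfig(step_amplitudes=amps,
                                            step_duration=1000.0,
                                            seed_base=seed))
        noisy = fi_protocol(p, ProtocolConfig(
            step_amplitudes=amps, step_duration=1000.0, repeats=15,
            noise_coefficient=coeff, seed_base=seed + 1))
        write_curve(det, outdir / f"fi_det_{label}.csv")
        write_curve(noisy, outdir / f"fi_noise_{label}.csv")
        axes[1].plot(amps, det.y, "--", color=color)
        axes[1].plot(amps, noisy.y, "-", color=color, label=label)
        ptrans = step_transition_amplitude(p, 100.0)
        pa = np.arange(ptrans - 120.0, ptrans + 90.0, 10.0)
        pn = spike_probability_protocol(p, ProtocolConfig(
            step_amplitudes=pa, step_duration=100.0, repeats=20,
            noise_coefficient=coeff, seed_base=seed + 2))
        write_curve(pn, outdir / f"pi_noise_{label}.csv")
        bfit = fit_boltzmann(pn.x, pn.y)
        metrics[label] = {"boltzmann_k": bfit.k,
                          "p02_shift": ptrans - bfit.P02_current}
        axes[2].plot(pn.x, pn.y, "o-", ms=3, color=color, label=label)
    write_json(metrics, outdir / "fig6_metrics.json")
    axes[0].set(xlabel="V (mV)", ylabel="R (MΩ)")
    axes[1].set(xlabel="I (pA)", ylabel="f (spikes/s)")
    axes[2].set(xlabel="I (pA)", ylabel="P(spike)")
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "fig6.png", dpi=150)
    plt.close(fig)


def fig7(outdir, seed: int = 0) -> None:
    """Phase-plane analysis and interval-fraction spike probability for
    the two spike-slope-factor regimes."""
    outdir = _mkdir(outdir)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    Vg = np.arange(-80.0, -45.0, 0.25)
    for DT, color in ((15.0, "r"), (2.0, "b")):
        p = ELIFParams(Delta_T=DT)
        I_dc = elif_rheobase(p) + 20.0
        pp = phase_plane_curve(p, I_dc, Vg)
        write_curve(pp, outdir / f"phase_plane_DT{DT:g}.csv")
        axes[0].plot(pp.x, pp.y, color=color, label=f"Δ_T = {DT:g}")
        coeff = calibrate_noise_coefficient(p, seed=seed)
        ip = studies.interval_probability_study(p, coeff, n_trials=300,
                                                seed=seed)
        write_curve(ip, outdir / f"interval_probability_DT{DT:g}.csv")
        axes[1].plot(ip.x, ip.y, "o-", ms=3, color=color,
                     label=f"Δ_T = {DT:g}")
    axes[0].axhline(0.0, color="0.7", lw=0.5)
    axes[0].set(xlabel="V (mV)", ylabel="dV/dt (mV/ms)")
    axes[1].set(xlabel="interval fraction", ylabel="P(spike in 50 ms)")
    for ax in axes:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "fig7.png", dpi=150)
    plt.close(fig)


def fig8(outdir, seed: int = 0) -> None:
    """Voltage-fluctuation SD versus mean voltage, and the noise-
    coefficient ladder (90:140:280)."""
    outdir = _mkdir(outdir)
    from .protocols import voltage_sd_vs_mean
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for DT, color in ((2.0, "b"), (15.0, "r")):
        p = ELIFParams(Delta_T=DT)
        coeff = calibrate_noise_coefficient(p, seed=seed)
        I_hold = holding_current(p, -75.0)
        dcs = I_hold + np.linspace(-120.0, 0.85 * (elif_rheobase(p)
                                                   - I_hold), 8)
        sd = voltage_sd_vs_mean(p, dcs, coeff, duration_s=5.0,
                                seed_base=seed)
        write_curve(sd, outdir / f"sd_vs_mean_DT{DT:g}.csv")
        axes[0].plot(sd.x, sd.y, "o-", color=color, label=f"Δ_T = {DT:g}")
    p15 = ELIFParams(Delta_T=15.0)
    c15 = calibrate_noise_coefficient(p15, seed=seed)
    base90 = c15 * 2.3 / 2.41  # ladder base: realized 2.3 mV SD
    ladder = studies.noise_scaling_study(p15, base90, seed=seed)
    write_json(ladder, outdir / "noise_ladder.json")
    axes[1].plot(ladder["ratios"], ladder["sd_mV"], "ks-")
    axes[0].set(xlabel="mean V (mV)", ylabel="SD (mV)")
    axes[0].legend(fontsize=8)
    axes[1].set(xlabel="coefficient ratio (vs 90)", ylabel="SD at -75 (mV)")
    fig.tight_layout()
    fig.savefig(outdir / "fig8.png", dpi=150)
    plt.close(fig)
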