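"""Figure-level study computations.

Each function here runs one self-contained piece of the computational
study — calibrate the stimulus, drive a model through a protocol, apply
the relevant fits — and returns plain dictionaries/curves ready for
serialization. The numbered drivers under ``analysis/``, the ``fluctmod
reproduce`` command and the acceptance script all call these, so every
reported number has exactly one implementation.

Model shorthand used throughout: ``elif15``/``elif2`` are the exponential
integrate-and-fire cell with spike slope factor 15 or 2 mV; ``+shunt``
adds the 15 nS linear conductance reversing at −75 mV.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .models import (ELIFParams, PassiveLIFParams, HHParams, ModelParams,
                     holding_current, elif_rheobase, input_resistance)
from .noise import DEFAULT_F_CUT
from .protocols import (ProtocolConfig, fi_protocol, fv_protocol,
                        first_spike_trajectory, isi_trajectory,
                        interval_fraction_probability,
                        amplitudes_for_rate_range, find_dc_for_mean_voltage,
                        CurveData)
from .analysis import (fit_power_law, fit_linear_gain,
                       rheobase_from_steps, fraction_above_midpoint,
                       ahp_half_duration)

__all__ = [
    "reference_models", "fv_study", "fv_band_metrics",
    "low_region_delta_study", "sd_at_mean_study", "resistance_profile",
    "trajectory_study", "vr_gain_sweep", "interval_probability_study",
    "noise_scaling_study",
]


def reference_models() -> Dict[str, ModelParams]:
    """The study's standing cast of models."""
    return {
        "elif15": ELIFParams(Delta_T=15.0),
        "elif5": ELIFParams(Delta_T=5.0),
        "elif2": ELIFParams(Delta_T=2.0),
        "elif15_shunt": ELIFParams(Delta_T=15.0, g_shunt=15.0),
        "elif2_shunt": ELIFParams(Delta_T=2.0, g_shunt=15.0),
        "passive": PassiveLIFParams(),
        "hh": HHParams(),
    }


def fv_study(params: ModelParams, seed: int = 0, f_lo: float = 1.5,
             f_hi: float = 62.0, n_levels: int = 30,
             step_duration: float = 3000.0,
             fit_band: tuple = (1.0, 60.0)) -> dict:
    """Deterministic f-V curve across a firing-rate range, plus its
    power-law fit and voltage span within ``fit_band`` (spikes/s)."""
    amps = amplitudes_for_rate_range(params, f_lo, f_hi, n=n_levels)
    cfg = ProtocolConfig(step_amplitudes=amps, step_duration=step_duration,
                         seed_base=seed)
    curve = fv_protocol(params, cfg)
    ok = (np.isfinite(curve.y) & np.isfinite(curve.x)
          & (curve.y >= fit_band[0]) & (curve.y <= fit_band[1]))
    fit = fit_power_law(curve.x[ok], curve.y[ok]) if ok.sum() >= 5 else None
    span = float(curve.x[ok].max() - curve.x[ok].min()) if ok.any() else None
    return {"curve": curve, "fit": fit, "span_mV": span,
            "band": fit_band, "n_points": int(ok.sum())}


def fv_band_metrics(params: ModelParams, **kw) -> dict:
    st = fv_study(params, **kw)
    out = {"span_mV": st["span_mV"]}
    if st["fit"] is not None:
        out.update(p=st["fit"].p, r2=st["fit"].r2, V_c=st["fit"].V_c)
    return out


def low_region_delta_study(params: ELIFParams, coefficient: float,
                           seed: int = 0, grid: float = 25.0,
                           n_repeats: int = 60,
                           step_duration: float = 1000.0) -> dict:
    """Fluctuation-induced change in initial firing rate at the
    deterministic f-I rheobase (the "low region" delta).

    Deterministic f-I on a ``grid`` pA amplitude ladder fixes the rheobase
    (first step with >= 4 spikes) and the rate there; ``n_repeats`` fresh
    noise realizations at that same amplitude give the noisy rate
    (spike-deficient trials count 0 spikes/s).
    """
    rheo_exact = elif_rheobase(params) - holding_current(params, -75.0)
    amps = np.arange(0.0, rheo_exact + 12 * grid, grid)
    cfg_det = ProtocolConfig(step_amplitudes=amps,
                             step_duration=step_duration, seed_base=seed)
    det = fi_protocol(params, cfg_det)
    rheo = rheobase_from_steps(amps, det.meta["spike_counts"][:, 0])
    cfg_noise = ProtocolConfig(step_amplitudes=np.array([rheo]),
                               step_duration=step_duration,
                               repeats=n_repeats,
                               noise_coefficient=coefficient,
                               seed_base=seed + 1)
    noisy = fi_protocol(params, cfg_noise)
    det_rate = det.y[int(np.searchsorted(amps, rheo))]
    det_rate = 0.0 if np.isnan(det_rate) else float(det_rate)
    reps = noisy.y_repeats[0]
    reps0 = np.where(np.isnan(reps), 0.0, reps)
    return {"rheobase_amp": float(rheo), "rheobase_exact": float(rheo_exact),
            "det_rate": det_rate, "noisy_rate": float(noisy.y[0]),
            "delta": float(noisy.y[0] - det_rate),
            "delta_sem": float(reps0.std(ddof=1) / np.sqrt(reps0.size)),
            "n_repeats": n_repeats, "det_curve": det}


def sd_at_mean_study(params: ModelParams, coefficient: float,
                     target_mean: float = -68.0, seed: int = 0,
                     n_seeds: int = 4, duration_s: float = 15.0) -> dict:
    """Sub-threshold voltage SD at a depolarized mean voltage.

    DC is titrated so the mean sub-threshold voltage (spikes excluded)
    reaches ``target_mean``; the SD is then averaged over ``n_seeds``
    independent ``duration_s`` stretches.
    """
    from .noise import generate_filtered_noise, subthreshold_sd
    from .models import simulate_model, steady_state_voltage
    from .protocols import trial_seed
    I_dc, _, _ = find_dc_for_mean_voltage(params, coefficient, target_mean,
                                          duration_s=duration_s,
                                          seed_base=seed)
    means, sds = [], []
    dur_ms = duration_s * 1e3 + 500.0
    for k in range(n_seeds):
        stim = generate_filtered_noise(dur_ms, 0.01, DEFAULT_F_CUT,
                                       coefficient,
                                       seed=trial_seed(seed, 500 + k),
                                       I_dc=I_dc)
        ss = steady_state_voltage(params, I_dc)
        tr = simulate_model(params, stim,
                            v0=ss if ss is not None else target_mean)
        m, s = subthreshold_sd(tr)
        means.append(m)
        sds.append(s)
    return {"I_dc": float(I_dc), "mean_V": float(np.mean(means)),
            "sd_mV": float(np.mean(sds)), "sd_sem": float(
                np.std(sds, ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1
            else 0.0}


def resistance_profile(params: ModelParams,
                       voltages: Sequence[float] = np.arange(-90., -59.,
                                                             2.5)) -> CurveData:
    """Steady-state input resistance versus holding voltage (5 mV clamp)."""
    R = [input_resistance(params, float(v)) for v in voltages]
    return CurveData(x=np.asarray(voltages, dtype=float),
                     y=np.asarray(R),
                     xlabel="V_mV", ylabel="R_MOhm",
                     meta={"protocol": "resistance_profile"})


def trajectory_study(params: ModelParams, seed: int = 0,
                     target_latency: float = 50.0,
                     target_rate: float = 4.0) -> dict:
    """First-spike and inter-spike-interval trajectory shape metrics."""
    cfg = ProtocolConfig(seed_base=seed)
    first = first_spike_trajectory(params, cfg,
                                   target_latency=target_latency)
    cycle = isi_trajectory(params, cfg, target_rate=target_rate)
    return {
        "first_spike": first,
        "isi_cycle": cycle,
        "frac_above_mid": fraction_above_midpoint(first.t, first.V_mean),
        "ahp_half_ms": ahp_half_duration(cycle.t, cycle.V_mean,
                                         cycle.meta["threshold_V"]),
        "period_ms": cycle.meta["period_ms"],
    }


def vr_gain_sweep(Delta_T: float, V_r_values: Sequence[float],
                  seed: int = 0, grid: float = 25.0,
                  n_levels: int = 12) -> list:
    """Deterministic f-I gain as a function of the reset voltage V_r."""
    out = []
    for vr in V_r_values:
        p = ELIFParams(Delta_T=Delta_T, V_r=float(vr))
        rheo = elif_rheobase(p) - holding_current(p, -75.0)
        amps = np.arange(max(rheo - grid, 0.0), rheo + n_levels * grid,
                         grid)
        cfg = ProtocolConfig(step_amplitudes=amps, step_duration=1000.0,
                             seed_base=seed)
        fi = fi_protocol(p, cfg)
        m = fit_linear_gain(amps, fi.y)
        out.append({"V_r": float(vr), "gain": m.gain, "gain_r2": m.gain_r2})
    return out


def interval_probability_study(params: ModelParams, coefficient: float,
                               fractions: Sequence[float] = np.arange(
                                   0.05, 1.0, 0.05),
                               n_trials: int = 1000, seed: int = 0) -> CurveData:
    """Phase-dependent spike probability along the ~4 Hz firing cycle."""
    return interval_fraction_probability(
        params, fractions, n_trials=n_trials, window=50.0,
        noise_coefficient=coefficient, target_rate=4.0, seed_base=seed)


def noise_scaling_study(params: ModelParams, base_coefficient: float,
                        ratios: Sequence[float] = (1.0, 140. / 90.,
                                                   280. / 90.),
                        seed: int = 0, duration_s: float = 15.0) -> dict:
    """Voltage-fluctuation SD at −75 mV for scaled noise coefficients
    (the 90 : 140 : 280 coefficient ladder)."""
    from .noise import generate_filtered_noise, subthreshold_sd
    from .models import simulate_model
    from .protocols import trial_seed
    I_hold = holding_current(params, -75.0)
    sds = []
    for k, r in enumerate(ratios):
        stim = generate_filtered_noise(duration_s * 1e3 + 500.0, 0.01,
                                       DEFAULT_F_CUT,
                                       base_coefficient * r,
                                       seed=trial_seed(seed, 900 + k),
                                       I_dc=I_hold)
        tr = simulate_model(params, stim, v0=-75.0)
        sds.append(subthreshold_sd(tr)[1])
    return {"ratios": list(map(float, ratios)),
            "sd_mV": list(map(float, sds))}
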