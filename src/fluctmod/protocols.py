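"""Stimulation protocols: f-I, spike-probability, f-V, trajectories,
interval-fraction probability, phase-plane and voltage-SD measurements.

Every protocol holds the model at −75 mV (via a constant bias equal to the
holding current) and reports step amplitudes *above* that bias, matching
the current-clamp convention of stepping from a holding state. Each trial
settles for ``pre_step_settle`` ms at the holding bias (with fluctuations
already on when the noise coefficient is non-zero) before the step.

Fresh noise seeds are drawn per trial from ``seed_base`` so repeats are
statistically independent and every output is reproducible bit-identically
from (config, seed_base).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from . import models as _m
from .models import (ELIFParams, HHParams, ModelParams, PassiveLIFParams,
                     SimulationTrace, SpikeTrain, simulate_model,
                     holding_current, steady_state_voltage)
from .noise import generate_filtered_noise, DEFAULT_F_CUT
from .analysis import spike_frequency_first3

__all__ = [
    "ProtocolConfig", "CurveData", "TrajectoryData", "ProtocolFailure",
    "fi_protocol", "spike_probability_protocol", "fv_protocol",
    "first_spike_trajectory", "isi_trajectory",
    "interval_fraction_probability", "phase_plane_curve",
    "voltage_sd_vs_mean", "spike_initiation_voltage", "steady_rate",
    "find_dc_for_rate", "find_dc_for_mean_voltage", "estimate_rheobase",
    "amplitudes_for_rate_range", "trial_seed",
]


class ProtocolFailure(RuntimeError):
    pass


@dataclass
class ProtocolConfig:
    """Shared protocol settings (amplitudes are pA above the holding bias)."""

    step_amplitudes: Sequence[float] = ()
    step_duration: float = 1000.0     # ms
    pre_step_settle: float = 1000.0   # ms
    repeats: int = 1
    noise_coefficient: float = 0.0
    f_cut: float = DEFAULT_F_CUT
    dt: float = _m.DEFAULT_DT
    seed_base: int = 0
    V_hold: float = -75.0
    min_spikes: int = 4
    clip_V: Optional[float] = None    # spike-waveform clip for voltage means
    clip_pad_ms: float = 2.0          # (None: the full trajectory counts)

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        amps = np.asarray(self.step_amplitudes, dtype=float)
        if amps.size and np.any(np.diff(amps) < 0):
            raise ValueError("step_amplitudes must be sorted ascending")
        self.step_amplitudes = amps


@dataclass
class CurveData:
    """Generic (x, y) curve with optional per-repeat values and metadata."""

    x: np.ndarray
    y: np.ndarray                      # NaN encodes "missing"
    y_repeats: Optional[np.ndarray] = None   # shape (len(x), repeats)
    xlabel: str = "x"
    ylabel: str = "y"
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({self.xlabel: self.x, self.ylabel: self.y})
        if self.y_repeats is not None:
            for j in range(self.y_repeats.shape[1]):
                df[f"rep{j}"] = self.y_repeats[:, j]
        return df


@dataclass
class TrajectoryData:
    """Voltage trajectory relative to an alignment point."""

    t: np.ndarray                 # ms relative to alignment
    V_mean: np.ndarray            # mV
    alignment: str                # "step_onset" or "ahp_trough"
    V_sem: Optional[np.ndarray] = None
    meta: Dict = field(default_factory=dict)


def trial_seed(seed_base: int, trial_index: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    return (seed_base * 9973 + trial_index * 7919 + 1) % (2 ** 31 - 1)


def _trial_stimulus(cfg: ProtocolConfig, I_hold: float, amplitude: float,
                    seed: int, total_ms: float) -> np.ndarray:
    n = int(round(total_ms / cfg.dt))
    if cfg.noise_coefficient > 0:
        stim = generate_filtered_noise(total_ms, cfg.dt, cfg.f_cut,
                                       cfg.noise_coefficient, seed=seed)
        I = stim.I_fluct.copy()
    else:
        I = np.zeros(n)
    I += I_hold
    on = int(round(cfg.pre_step_settle / cfg.dt))
    I[on:] += amplitude
    return I


def run_step_trial(params: ModelParams, cfg: ProtocolConfig, I_hold: float,
                   amplitude: float, seed: int) -> SimulationTrace:
    """One settle + step trial; returned spike times are re-based to step
    onset (spikes during the settle window are dropped)."""
    total = cfg.pre_step_settle + cfg.step_duration
    I = _trial_stimulus(cfg, I_hold, amplitude, seed, total)
    tr = simulate_model(params, I, v0=cfg.V_hold, dt=cfg.dt, seed=seed)
    t_on = cfg.pre_step_settle
    times = tr.spikes.times
    tr.spikes = SpikeTrain(times[times >= t_on] - t_on)
    tr.meta_t_on = t_on  # type: ignore[attr-defined]
    return tr


# --- f-I and spike-probability protocols -----------------------------------

def fi_protocol(params: ModelParams, cfg: ProtocolConfig) -> CurveData:
    """Spike frequency (first three ISIs) versus step amplitude.

    With noise, each amplitude is repeated ``cfg.repeats`` times with fresh
    seeds; the curve's ``y`` is the mean rate with spike-deficient trials
    (< 4 spikes) counted as 0 spikes/s, and per-repeat rates (NaN when
    undefined) are kept in ``y_repeats``. Deterministic runs store NaN for
    amplitudes with fewer than four spikes.
    """
    I_hold = holding_current(params, cfg.V_hold)
    amps = cfg.step_amplitudes
    reps = cfg.repeats if cfg.noise_coefficient > 0 else 1
    rates = np.full((amps.size, reps), np.nan)
    counts = np.zeros((amps.size, reps), dtype=int)
    k = 0
    for i, amp in enumerate(amps):
        for j in range(reps):
            tr = run_step_trial(params, cfg, I_hold, amp,
                                trial_seed(cfg.seed_base, k))
            k += 1
            counts[i, j] = len(tr.spikes)
            f = spike_frequency_first3(tr.spikes)
            if f is not None:
                rates[i, j] = f
    if cfg.noise_coefficient > 0:
        y = np.nanmean(np.where(np.isnan(rates), 0.0, rates), axis=1)
    else:
        y = rates[:, 0]
    return CurveData(x=amps, y=y, y_repeats=rates,
                     xlabel="I_pA", ylabel="f_spikes_per_s",
                     meta={"spike_counts": counts, "I_hold": I_hold,
                           "config": cfg, "protocol": "fi"})


def spike_probability_protocol(params: ModelParams,
                               cfg: ProtocolConfig) -> CurveData:
    """Probability of >= 1 spike during a 100 ms step, per amplitude."""
    cfg = replace(cfg, step_duration=cfg.step_duration or 100.0)
    I_hold = holding_current(params, cfg.V_hold)
    amps = cfg.step_amplitudes
    probs = np.zeros(amps.size)
    hits = np.zeros((amps.size, cfg.repeats))
    k = 0
    for i, amp in enumerate(amps):
        for j in range(cfg.repeats):
            tr = run_step_trial(params, cfg, I_hold, amp,
                                trial_seed(cfg.seed_base, k))
            k += 1
            hits[i, j] = 1.0 if len(tr.spikes) >= 1 else 0.0
        probs[i] = hits[i].mean()
    return CurveData(x=amps, y=probs, y_repeats=hits,
                     xlabel="I_pA", ylabel="P_spike",
                     meta={"I_hold": I_hold, "config": cfg,
                           "protocol": "spike_probability"})


# --- f-V protocol -----------------------------------------------------------

def _clipped_mean_voltage(tr: SimulationTrace, t0: float, t1: float,
                          clip_V: Optional[float], pad_ms: float,
                          t_offset: float = 0.0) -> float:
    """Mean voltage over [t0, t1] (trial time = step time + t_offset),
    excluding samples above clip_V plus pad_ms on either side when a clip
    voltage is set."""
    dt = tr.dt
    i0 = int(round((t0 + t_offset) / dt))
    i1 = int(round((t1 + t_offset) / dt))
    V = tr.V[i0:i1 + 1]
    if clip_V is None:
        return float(V.mean()) if V.size else math.nan
    bad = V > clip_V
    if bad.any():
        pad = int(round(pad_ms / dt))
        idx = np.where(bad)[0]
        mask = np.zeros(V.size, dtype=bool)
        for i in idx:
            mask[max(0, i - pad): i + pad + 1] = True
        V = V[~mask]
    if V.size == 0:
        return math.nan
    return float(V.mean())


def fv_protocol(params: ModelParams, cfg: ProtocolConfig) -> CurveData:
    """Firing rate versus mean membrane voltage.

    Per amplitude: frequency from the first three ISIs; voltage = mean over
    the window [first spike, fourth spike]. By default the mean runs over
    the full trajectory (including the spike escape up to the reset cutoff);
    setting ``cfg.clip_V`` excludes samples above that voltage padded by
    ``clip_pad_ms`` on either side.
    """
    I_hold = holding_current(params, cfg.V_hold)
    amps = cfg.step_amplitudes
    reps = cfg.repeats if cfg.noise_coefficient > 0 else 1
    f_out = np.full((amps.size, reps), np.nan)
    v_out = np.full((amps.size, reps), np.nan)
    k = 0
    t_on = cfg.pre_step_settle
    for i, amp in enumerate(amps):
        for j in range(reps):
            tr = run_step_trial(params, cfg, I_hold, amp,
                                trial_seed(cfg.seed_base, k))
            k += 1
            f = spike_frequency_first3(tr.spikes)
            if f is None:
                continue
            t_first, t_fourth = tr.spikes.times[0], tr.spikes.times[3]
            f_out[i, j] = f
            v_out[i, j] = _clipped_mean_voltage(
                tr, t_first, t_fourth, cfg.clip_V, cfg.clip_pad_ms,
                t_offset=t_on)
    f_mean = np.nanmean(f_out, axis=1) if reps > 1 else f_out[:, 0]
    v_mean = np.nanmean(v_out, axis=1) if reps > 1 else v_out[:, 0]
    return CurveData(x=v_mean, y=f_mean,
                     xlabel="V_mV", ylabel="f_spikes_per_s",
                     meta={"amplitudes": amps, "I_hold": I_hold,
                           "config": cfg, "protocol": "fv"})


# --- rate / latency search helpers -----------------------------------------

def spike_initiation_voltage(params: ModelParams) -> float:
    """Nominal voltage at which a spike initiates (trajectory endpoint)."""
    if isinstance(params, ELIFParams):
        return params.V_T
    if isinstance(params, PassiveLIFParams):
        return params.V_thresh
    return -40.0  # H-H: upstroke take-off region


def steady_rate(params: ModelParams, I_dc: float,
                dt: float = _m.DEFAULT_DT, max_duration: float = 8000.0,
                v0: Optional[float] = None) -> float:
    """Steady firing rate (spikes/s) at absolute DC current.

    Simulates until at least 8 spikes are seen (or max_duration) and
    returns 1000 / mean(last three ISIs); 0.0 when firing never becomes
    periodic within the window.
    """
    if v0 is None:
        ss = steady_state_voltage(params, I_dc)
        v0 = ss if ss is not None else -75.0
    dur = 3000.0
    while True:
        tr = simulate_model(params, I_dc, v0=v0, dt=dt, duration=dur)
        if len(tr.spikes) >= 8 or dur >= max_duration:
            break
        dur = min(dur * 2.0, max_duration)
    if len(tr.spikes) < 5:
        return 0.0
    isis = tr.spikes.isis()[-3:]
    return float(1000.0 / isis.mean())


def find_dc_for_rate(params: ModelParams, target_rate: float,
                     tol: float = 0.2, dt: float = _m.DEFAULT_DT,
                     I_lo: float = 0.0, I_hi: float = 2000.0,
                     max_iter: int = 60) -> float:
    """Absolute DC current producing a steady rate within ±tol of target."""
    lo, hi = I_lo, None
    I = max(I_lo, 1.0)
    # grow until above target
    for _ in range(30):
        r = steady_rate(params, I, dt=dt)
        if r > target_rate:
            hi = I
            break
        lo = I
        I = I * 2.0 if I > 0 else 50.0
        if I > I_hi:
            break
    if hi is None:
        raise ProtocolFailure(
            f"target rate {target_rate} spikes/s not attainable below "
            f"{I_hi} pA")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = steady_rate(params, mid, dt=dt)
        if abs(r - target_rate) <= tol:
            return mid
        if r > target_rate:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-9 * max(abs(hi), 1.0):
            # f-I discontinuity (threshold-like onset): the target rate
            # is unattainable; the smallest spiking current is the
            # closest achievable operating point
            return hi
    raise ProtocolFailure(
        f"rate bisection did not reach ±{tol} spikes/s of {target_rate}")


def estimate_rheobase(params: ModelParams, lo: float = 0.0,
                      hi: float = 4000.0, tol: float = 0.5,
                      dt: float = _m.DEFAULT_DT,
                      probe_duration: float = 2000.0,
                      min_spikes: int = 2) -> float:
    """Bisection estimate of the deterministic rheobase (absolute DC, pA)
    via repetitive spiking within ``probe_duration``."""

    def spiking(I):
        ss = steady_state_voltage(params, I)
        v0 = ss if ss is not None else -75.0
        tr = simulate_model(params, I, v0=v0, dt=dt,
                            duration=probe_duration)
        return len(tr.spikes) >= min_spikes

    if spiking(lo):
        return lo
    if not spiking(hi):
        raise ProtocolFailure(f"no spiking up to {hi} pA")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spiking(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def step_transition_amplitude(params: ModelParams, step_duration: float,
                              min_spikes: int = 1, V_hold: float = -75.0,
                              tol: float = 1.0, hi: float = 4000.0,
                              dt: float = _m.DEFAULT_DT) -> float:
    """Smallest step amplitude (pA above the holding bias) eliciting
    >= min_spikes spikes within ``step_duration`` from a V_hold hold
    (deterministic; bisection to ``tol`` pA)."""
    I_hold = holding_current(params, V_hold)
    n = int(round(step_duration / dt))

    def spiking(amp: float) -> bool:
        tr = simulate_model(params, np.full(n, I_hold + amp), v0=V_hold,
                            dt=dt)
        return len(tr.spikes) >= min_spikes

    lo = 0.0
    if spiking(lo):
        return 0.0
    amp = 100.0
    while not spiking(amp):
        lo = amp
        amp *= 2.0
        if amp > hi:
            raise ProtocolFailure(f"no spiking up to {hi} pA step")
    hi_amp = amp
    while hi_amp - lo > tol:
        mid = 0.5 * (lo + hi_amp)
        if spiking(mid):
            hi_amp = mid
        else:
            lo = mid
    return 0.5 * (lo + hi_amp)


def amplitudes_for_rate_range(params: ModelParams, f_min: float,
                              f_max: float, n: int = 30,
                              V_hold: float = -75.0,
                              dt: float = _m.DEFAULT_DT) -> np.ndarray:
    """Step amplitudes (above holding bias) spanning steady rates
    [f_min, f_max], linearly spaced in current."""
    I_hold = holding_current(params, V_hold)
    I_lo = find_dc_for_rate(params, f_min, tol=max(0.1, 0.05 * f_min), dt=dt)
    I_hi = find_dc_for_rate(params, f_max, tol=max(0.2, 0.02 * f_max), dt=dt)
    return np.linspace(I_lo, I_hi, n) - I_hold


# --- trajectories -----------------------------------------------------------

def first_spike_trajectory(params: ModelParams, cfg: ProtocolConfig,
                           target_latency: float = 50.0,
                           latency_tol: float = 2.0) -> TrajectoryData:
    """Deterministic voltage trajectory from step onset to spike threshold
    for a step whose first-spike latency matches ``target_latency``.

    The step amplitude is found by bisection (latency is monotone
    decreasing in amplitude). The trajectory is truncated at the model's
    spike-initiation voltage so that integrate-and-fire blow-up samples do
    not dominate shape metrics.
    """
    I_hold = holding_current(params, cfg.V_hold)
    dt = cfg.dt
    dur = max(6.0 * target_latency, 500.0)

    def latency(amp: float) -> float:
        I = np.full(int(round(dur / dt)), I_hold + amp)
        tr = simulate_model(params, I, v0=cfg.V_hold, dt=dt)
        if len(tr.spikes) == 0:
            return math.inf
        return float(tr.spikes.times[0])

    lo, hi = 0.0, None
    amp = 100.0
    for _ in range(40):
        lat = latency(amp)
        if lat <= target_latency:
            hi = amp
            break
        lo = amp
        amp *= 2.0
        if amp > 1e6:
            break
    if hi is None:
        raise ProtocolFailure("target latency not attainable: amplitude "
                              "range exhausted")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        lat = latency(mid)
        if abs(lat - target_latency) <= latency_tol:
            amp = mid
            break
        if lat > target_latency:
            lo = mid
        else:
            hi = mid
    else:
        raise ProtocolFailure(
            f"latency bisection did not reach ±{latency_tol} ms")

    I = np.full(int(round(dur / dt)), I_hold + amp)
    tr = simulate_model(params, I, v0=cfg.V_hold, dt=dt)
    v_end = spike_initiation_voltage(params)
    i_spike = int(round(tr.spikes.times[0] / dt)) if len(tr.spikes) \
        else tr.V.size
    crossing = np.where(tr.V[:i_spike] >= v_end)[0]
    # the spike sample itself holds the post-reset voltage: stop before it
    i_end = int(crossing[0]) if crossing.size else max(i_spike - 1, 1)
    return TrajectoryData(t=tr.t[:i_end + 1], V_mean=tr.V[:i_end + 1].copy(),
                          alignment="step_onset",
                          meta={"amplitude": amp, "latency_ms": lat,
                                "threshold_V": v_end, "I_hold": I_hold})


def _steady_cycle(params: ModelParams, I_dc: float, dt: float
                  ) -> SimulationTrace:
    """Simulate long enough for periodic firing and return the trace."""
    ss = steady_state_voltage(params, I_dc)
    v0 = ss if ss is not None else -75.0
    dur = 3000.0
    while True:
        tr = simulate_model(params, I_dc, v0=v0, dt=dt, duration=dur)
        if len(tr.spikes) >= 8 or dur >= 16000.0:
            return tr
        dur *= 2.0


def isi_trajectory(params: ModelParams, cfg: ProtocolConfig,
                   target_rate: float = 4.0,
                   rate_tol: float = 0.2) -> TrajectoryData:
    """One steady-state inter-spike cycle at a target firing rate, aligned
    at the AHP trough (the voltage minimum of the cycle)."""
    I_dc = find_dc_for_rate(params, target_rate, tol=rate_tol, dt=cfg.dt)
    tr = _steady_cycle(params, I_dc, cfg.dt)
    if len(tr.spikes) < 3:
        raise ProtocolFailure("not enough spikes for a steady cycle")
    t0, t1 = tr.spikes.times[-2], tr.spikes.times[-1]
    i0, i1 = int(round(t0 / cfg.dt)), int(round(t1 / cfg.dt))
    Vc = tr.V[i0:i1]
    i_trough = int(np.argmin(Vc))
    t = (np.arange(Vc.size) - i_trough) * cfg.dt
    return TrajectoryData(
        t=t[i_trough:], V_mean=Vc[i_trough:].copy(), alignment="ahp_trough",
        meta={"I_dc": I_dc, "period_ms": t1 - t0,
              "threshold_V": spike_initiation_voltage(params),
              "V_trough": float(Vc[i_trough]),
              "full_cycle_V": Vc.copy(), "i_trough": i_trough})


# --- interval-fraction spike probability -----------------------------------

def interval_fraction_probability(params: ModelParams,
                                  fraction_grid: Sequence[float],
                                  n_trials: int = 1000,
                                  window: float = 50.0,
                                  noise_coefficient: float = 0.0,
                                  target_rate: float = 4.0,
                                  dt: float = _m.DEFAULT_DT,
                                  f_cut: float = DEFAULT_F_CUT,
                                  seed_base: int = 0,
                                  I_dc: Optional[float] = None) -> CurveData:
    """Probability that fluctuations evoke a spike within ``window`` ms,
    as a function of phase along the deterministic inter-spike cycle.

    The model fires periodically at ``target_rate`` under DC alone; at each
    interval fraction the full deterministic state is frozen and used as
    the initial condition for ``n_trials`` independent noisy simulations.
    """
    if I_dc is None:
        I_dc = find_dc_for_rate(params, target_rate, dt=dt)
    tr = _steady_cycle(params, I_dc, dt)
    t0, t1 = tr.spikes.times[-2], tr.spikes.times[-1]
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    period = t1 - t0
    fractions = np.asarray(fraction_grid, dtype=float)
    probs = np.empty(fractions.size)
    n_win = int(round(window / dt))
    for fi, frac in enumerate(fractions):
        idx = min(i0 + int(frac * (i1 - i0)), i1 - 1)
        v_init = float(tr.V[idx])
        n_init = float(tr.aux[idx]) if tr.aux is not None else None
        hits = 0
        for j in range(n_trials):
            seed = trial_seed(seed_base, fi * n_trials + j)
            if noise_coefficient > 0:
                stim = generate_filtered_noise(window, dt, f_cut,
                                               noise_coefficient, seed=seed)
                I = stim.I_fluct + I_dc
            else:
                I = np.full(n_win, I_dc)
            if n_init is None:
                trial = simulate_model(params, I, v0=v_init, dt=dt)
            else:
                trial = _simulate_hh_from_state(params, I, v_init, n_init, dt)
            if len(trial.spikes) >= 1:
                hits += 1
            if noise_coefficient == 0:
                # deterministic: one trial decides the 0/1 outcome
                hits *= n_trials
                break
        probs[fi] = hits / n_trials
    return CurveData(x=fractions, y=probs,
                     xlabel="interval_fraction", ylabel="P_spike",
                     meta={"I_dc": I_dc, "period_ms": period,
                           "window_ms": window, "n_trials": n_trials,
                           "noise_coefficient": noise_coefficient,
                           "protocol": "interval_fraction_probability"})


def _simulate_hh_from_state(params: HHParams, I, v0, n0, dt):
    from ._kernels import hh_euler
    from .analysis import detect_spikes_array
    V, aux = hh_euler(v0, n0, dt, np.asarray(I, dtype=float), params.C,
                      params.g_Na, params.g_Nap, params.g_K, params.g_leak,
                      params.E_Na, params.E_K, params.E_L, params.tau_n,
                      params.act_m[0], params.act_m[1],
                      params.act_n[0], params.act_n[1],
                      params.act_p[0], params.act_p[1],
                      params.g_inh, params.E_inh)
    spikes = SpikeTrain(detect_spikes_array(V, dt))
    t = np.arange(V.size) * dt
    return SimulationTrace(t=t, V=V, spikes=spikes, dt=dt, aux=aux,
                           params_ref=params)


# --- phase plane and voltage-SD scans --------------------------------------

def phase_plane_curve(params: ModelParams, I_dc: float,
                      V_grid: Sequence[float]) -> CurveData:
    """dV/dt (mV/ms) of the deterministic dynamics on a voltage grid
    (H-H gating at steady state)."""
    V = np.asarray(V_grid, dtype=float)
    dvdt = (params.rhs_current(V) + I_dc) / params.C
    return CurveData(x=V, y=dvdt, xlabel="V_mV", ylabel="dVdt_mV_per_ms",
                     meta={"I_dc": I_dc, "protocol": "phase_plane"})


def voltage_sd_vs_mean(params: ModelParams, I_dc_grid: Sequence[float],
                       noise_coefficient: float,
                       duration_s: float = 15.0,
                       dt: float = _m.DEFAULT_DT,
                       f_cut: float = DEFAULT_F_CUT,
                       seed_base: int = 0) -> CurveData:
    """(mean sub-threshold V, SD of sub-threshold V) per absolute DC level,
    measured over ``duration_s`` seconds with spike-adjacent samples
    excluded."""
    from .noise import subthreshold_sd
    means, sds = [], []
    dur_ms = duration_s * 1e3 + 500.0  # extra settle window is discarded
    for k, I_dc in enumerate(I_dc_grid):
        ss = steady_state_voltage(params, I_dc)
        v0 = ss if ss is not None else -75.0
        stim = generate_filtered_noise(dur_ms, dt, f_cut, noise_coefficient,
                                       seed=trial_seed(seed_base, k),
                                       I_dc=I_dc)
        tr = simulate_model(params, stim, v0=v0, dt=dt)
        m, s = subthreshold_sd(tr)
        means.append(m)
        sds.append(s)
    return CurveData(x=np.asarray(means), y=np.asarray(sds),
                     xlabel="mean_V_mV", ylabel="SD_mV",
                     meta={"I_dc_grid": np.asarray(I_dc_grid, dtype=float),
                           "noise_coefficient": noise_coefficient,
                           "protocol": "voltage_sd_vs_mean"})


def find_dc_for_mean_voltage(params: ModelParams, noise_coefficient: float,
                             target_mean: float, duration_s: float = 15.0,
                             tol: float = 0.15, dt: float = _m.DEFAULT_DT,
                             f_cut: float = DEFAULT_F_CUT,
                             seed_base: int = 0, max_iter: int = 8
                             ) -> tuple[float, float, float]:
    """Absolute DC such that the mean sub-threshold voltage under noise is
    within ``tol`` mV of ``target_mean``. Returns (I_dc, mean, sd)."""
    from .noise import subthreshold_sd
    I_dc = -float(params.rhs_current(target_mean))
    dur_ms = duration_s * 1e3 + 500.0
    for it in range(max_iter):
        stim = generate_filtered_noise(dur_ms, dt, f_cut, noise_coefficient,
                                       seed=trial_seed(seed_base, 101 + it),
                                       I_dc=I_dc)
        ss = steady_state_voltage(params, I_dc)
        v0 = ss if ss is not None else target_mean
        tr = simulate_model(params, stim, v0=v0, dt=dt)
        m, s = subthreshold_sd(tr)
        if abs(m - target_mean) <= tol:
            return I_dc, m, s
        # local conductance estimate converts the voltage error to current
        g_eff = -float(np.gradient(params.rhs_current(
            np.array([m - 0.5, m, m + 0.5])), 0.5)[1])
        g_eff = max(g_eff, 1.0)
        I_dc += (target_mean - m) * g_eff
    raise ProtocolFailure(
        f"mean voltage {m:.2f} mV did not converge to {target_mean} mV")
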