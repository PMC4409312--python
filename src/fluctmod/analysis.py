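"""Statistics and curve fits on spike trains, traces and I/O curves.

Conventions shared with the experimental literature this package targets:

* spike frequency = mean of the reciprocals of the first three inter-spike
  intervals (undefined for fewer than four spikes);
* rheobase = smallest step amplitude eliciting at least four spikes from a
  −75 mV hold (with noise: the smallest amplitude where the median repeat
  does);
* gain = ordinary least-squares slope of the f-I relationship;
* spike-probability curves are fit with a rising Boltzmann
  P(I) = 1/(1 + exp(−(I − I_half)/k)), with the stochastic rheobase defined
  as the current giving P = 0.2;
* f-V curves are fit with a bounded power law f = a (V − V_c)^p + b, a ≥ 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.stats import linregress

from .models import SpikeTrain, SimulationTrace

__all__ = [
    "detect_spikes", "detect_spikes_array", "spike_frequency_first3",
    "rheobase_from_steps", "fit_linear_gain", "region_deltas",
    "fit_boltzmann", "fit_power_law", "fraction_above_midpoint",
    "ahp_half_duration", "BoltzmannFit", "PowerLawFit", "FIMetrics",
    "FitFailure", "MissingRheobase", "boltzmann", "power_law",
]

DEFAULT_SPIKE_THRESHOLD = -20.0  # mV, H-H threshold crossing
DEFAULT_REFRACTORY = 2.0         # ms


class FitFailure(RuntimeError):
    pass


class MissingRheobase(ValueError):
    pass


# --- spike detection and frequencies ---------------------------------------

def detect_spikes_array(V: np.ndarray, dt: float,
                        threshold: float = DEFAULT_SPIKE_THRESHOLD,
                        refractory: float = DEFAULT_REFRACTORY) -> np.ndarray:
    """Upward threshold-crossing times (ms) separated by >= refractory."""
    above = V >= threshold
    crossings = np.where(~above[:-1] & above[1:])[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    times = crossings * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def detect_spikes(trace: SimulationTrace,
                  threshold: float = DEFAULT_SPIKE_THRESHOLD,
                  refractory: float = DEFAULT_REFRACTORY) -> SpikeTrain:
    """Spike train from a voltage trace by upward threshold crossing.

    Integrate-and-fire traces carry reset-event spikes already; this is the
    detector for the H-H model (or external recordings).
    """
    return SpikeTrain(detect_spikes_array(trace.V, trace.dt,
                                          threshold, refractory))


def spike_frequency_first3(spikes: SpikeTrain,
                           reciprocal_of_mean: bool = False
                           ) -> Optional[float]:
    """Mean of the first three reciprocal ISIs, in spikes/s.

    Returns ``None`` with fewer than four spikes. ``reciprocal_of_mean``
    switches to 1/mean(ISI) over the same three intervals (alternative
    reading of the convention; off by default).
    """
    if len(spikes) < 4:
        return None
    isis_s = spikes.isis()[:3] * 1e-3
    if reciprocal_of_mean:
        return float(1.0 / isis_s.mean())
    return float(np.mean(1.0 / isis_s))


# --- f-I curve metrics ------------------------------------------------------

def rheobase_from_steps(amplitudes: np.ndarray, spike_counts: np.ndarray,
                        min_spikes: int = 4) -> float:
    """Smallest amplitude whose trial(s) produced >= min_spikes spikes.

    ``spike_counts`` may be 1-D (deterministic, one trial per amplitude) or
    2-D (amplitudes x repeats); with repeats, the median count across
    repeats must reach ``min_spikes``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    counts = np.asarray(spike_counts, dtype=float)
    if counts.ndim == 2:
        counts = np.median(counts, axis=1)
    ok = np.where(counts >= min_spikes)[0]
    if ok.size == 0:
        raise MissingRheobase("no amplitude elicited enough spikes")
    return float(amplitudes[ok[0]])


@dataclass
class FIMetrics:
    gain: float                      # spikes/(pA s)
    gain_r2: float
    rheobase: Optional[float] = None  # pA
    initial_rate: Optional[float] = None
    region_currents: Dict[str, float] = field(default_factory=dict)


def fit_linear_gain(amplitudes, frequencies) -> FIMetrics:
    """OLS slope of the f-I relationship over all defined points."""
    I = np.asarray(amplitudes, dtype=float)
    f = np.array([np.nan if v is None else v for v in frequencies],
                 dtype=float)
    ok = np.isfinite(f)
    if ok.sum() < 3:
        raise FitFailure("need at least 3 defined f-I points")
    res = linregress(I[ok], f[ok])
    return FIMetrics(gain=float(res.slope), gain_r2=float(res.rvalue ** 2))


def _interp_rate(amplitudes, rates, I):
    """Linear interpolation of the f-I curve, treating missing as 0 below
    the first defined point."""
    I_arr = np.asarray(amplitudes, dtype=float)
    r = np.array([0.0 if v is None or not np.isfinite(v) else v
                  for v in rates], dtype=float)
    return float(np.interp(I, I_arr, r))


def region_deltas(amplitudes, det_rates, noisy_rates,
                  rheobase: float) -> Dict[str, Optional[float]]:
    """Fluctuation-induced rate change at low/mid/high f-I regions.

    low = deterministic rheobase current; mid and high = currents where the
    deterministic curve reaches +15 and +25 spikes/s above the rate at
    rheobase (linear interpolation). Delta = mean noisy rate minus
    deterministic rate at each current; ``None`` for a region beyond the
    deterministic curve's span.
    """
    det = np.array([np.nan if v is None else v for v in det_rates],
                   dtype=float)
    I_arr = np.asarray(amplitudes, dtype=float)
    f0 = _interp_rate(I_arr, det, rheobase)
    out: Dict[str, Optional[float]] = {}
    targets = {"low": f0, "mid": f0 + 15.0, "high": f0 + 25.0}
    ok = np.isfinite(det)
    for name, f_target in targets.items():
        if name == "low":
            I_at = rheobase
        else:
            reach = ok & (det >= f_target)
            if not reach.any():
                out[name] = None
                continue
            # invert the deterministic curve on its defined points
            I_at = float(np.interp(f_target, det[ok], I_arr[ok]))
        out[name] = (_interp_rate(I_arr, noisy_rates, I_at)
                     - _interp_rate(I_arr, det, I_at))
    return out


# --- Boltzmann spike-probability fit ---------------------------------------

def boltzmann(I, I_half, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(I, dtype=float) - I_half) / k))


@dataclass
class BoltzmannFit:
    I_half: float    # pA
    k: float         # pA; larger = shallower
    r2: float
    P02_current: float
    degenerate: bool = False

    @classmethod
    def from_params(cls, I_half, k, r2, degenerate=False):
        return cls(I_half=I_half, k=k, r2=r2,
                   P02_current=I_half + k * math.log(0.2 / 0.8),
                   degenerate=degenerate)


def fit_boltzmann(amplitudes, probabilities) -> BoltzmannFit:
    """Least-squares Boltzmann fit to a spike-probability curve.

    Unweighted least squares. A near-step curve (transition narrower than
    the amplitude spacing) is fit but flagged degenerate.
    """
    I = np.asarray(amplitudes, dtype=float)
    P = np.asarray(probabilities, dtype=float)
    if I.size < 4:
        raise FitFailure("need >= 4 amplitudes for a Boltzmann fit")
    if P.min() < -1e-9 or P.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    i_half_guess = float(np.interp(0.5, P + 1e-12 * np.arange(P.size), I))
    span = max(I.max() - I.min(), 1.0)
    try:
        popt, _ = curve_fit(boltzmann, I, P,
                            p0=[i_half_guess, span / 10.0],
                            bounds=([I.min() - span, 1e-6],
                                    [I.max() + span, 10.0 * span]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitFailure(f"Boltzmann fit did not converge: {exc}") from exc
    resid = P - boltzmann(I, *popt)
    ss_tot = float(np.sum((P - P.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    spacing = np.min(np.diff(np.sort(I))) if I.size > 1 else span
    degenerate = popt[1] < 0.25 * spacing
    return BoltzmannFit.from_params(float(popt[0]), float(popt[1]), r2,
                                    degenerate=degenerate)


# --- power-law f-V fit ------------------------------------------------------

def power_law(V, a, V_c, p, b):
    V = np.asarray(V, dtype=float)
    x = np.clip(V - V_c, 0.0, None)
    return a * x ** p + b


@dataclass
class PowerLawFit:
    a: float
    V_c: float     # mV, onset voltage
    p: float       # exponent
    b: float       # spikes/s offset
    r2: float


def fit_power_law(V, f, p_starts=(1.0, 1.5, 2.0),
                  vc_offsets=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0)) -> PowerLawFit:
    """Bounded least-squares power-law fit f = a (V − V_c)^p + b.

    Constraints: a >= 1 and V_c <= min(V) (the onset voltage cannot exceed
    the lowest voltage that produced spikes). Multi-start over a grid of
    initial (V_c, p) pairs; three-parameter power laws are riddled with
    local minima, so the best of all starts is returned.
    """
    V = np.asarray(V, dtype=float)
    f = np.asarray(f, dtype=float)
    ok = np.isfinite(V) & np.isfinite(f)
    V, f = V[ok], f[ok]
    if V.size < 5:
        raise FitFailure("need >= 5 points for a power-law fit")
    vmin = float(V.min())

    def resid(theta):
        a, vc, p, b = theta
        return power_law(V, a, vc, p, b) - f

    lb = [1.0, vmin - 100.0, 0.05, 0.0]
    ub = [np.inf, vmin - 1e-6, 8.0, max(float(f.max()), 1.0)]
    best = None
    for dv in vc_offsets:
        for p0 in p_starts:
            vc0 = vmin - dv
            a0 = max((f.max() - f.min())
                     / max((V.max() - vc0) ** p0, 1e-12), 1.0)
            x0 = np.array([a0, vc0, p0, max(float(f.min()), 0.0)])
            x0 = np.minimum(np.maximum(x0, lb), ub)
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub),
                                    max_nfev=20000)
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailure("power-law fit did not converge from any start")
    a, vc, p, b = best.x
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(a=float(a), V_c=float(vc), p=float(p), b=float(b),
                       r2=float(r2))


# --- trajectory shape metrics ----------------------------------------------

def fraction_above_midpoint(t: np.ndarray, V: np.ndarray) -> float:
    """Fraction of time a rising trajectory spends above its midpoint.

    Midpoint = (V_start + V_end)/2. A value near 0.5 indicates a linear
    ramp; an exponential approach that plateaus early gives values near 1.
    """
    V = np.asarray(V, dtype=float)
    if V.size < 3:
        raise ValueError("trajectory too short")
    mid = 0.5 * (V[0] + V[-1])
    return float(np.mean(V > mid))


def ahp_half_duration(t: np.ndarray, V: np.ndarray,
                      threshold_V: float) -> Optional[float]:
    """Time (ms) from the AHP trough to the trough-threshold midpoint.

    ``t``/``V`` describe one inter-spike cycle aligned at the AHP trough
    (t[0] at the trough); ``threshold_V`` is the voltage at which the next
    spike initiates. Returns ``None`` when the midpoint is never crossed.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    v_mid = 0.5 * (V[0] + threshold_V)
    above = np.where(V >= v_mid)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        return 0.0
    # linear interpolation between the bracketing samples
    frac = (v_mid - V[i - 1]) / (V[i] - V[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - t[0])
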