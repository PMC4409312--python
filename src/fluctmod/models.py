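"""Neuron models and their steady-state characterizations.

Three single-compartment models are provided, all integrated with a forward
Euler scheme at dt = 0.01 ms (the reference integrator):

* :class:`ELIFParams` — exponential leaky integrate-and-fire (eLIF). The
  exponential term ``gL * Delta_T * exp((V - V_T)/Delta_T)`` approximates the
  sub-threshold activation of Na+ conductance; the spike slope factor
  ``Delta_T`` sets how gradually membrane resistance grows with
  depolarization. Voltage diverges past V_T and is reset to V_r once it
  reaches ``V_spike_cut`` (0 mV), at which point a spike is recorded.
* :class:`PassiveLIFParams` — standard LIF: a linear membrane with an
  artificial threshold (−55 mV) and reset (−65 mV).
* :class:`HHParams` — reduced two-variable Hodgkin–Huxley model with
  instantaneous transient-Na+ activation (m), persistent-Na+ activation (p),
  a single recovery variable n (K+ activation, with h ≈ 1 − n), and a leak.
  The persistent Na+ conductance g_Nap produces the voltage-dependent rise
  in input resistance that the eLIF mimics with a large Delta_T.

Units throughout: mV, ms, pA, nS, pF.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from ._kernels import elif_euler, passive_lif_euler, hh_euler

__all__ = [
    "ELIFParams", "PassiveLIFParams", "HHParams", "ModelParams",
    "SpikeTrain", "SimulationTrace",
    "simulate_model", "steady_state_voltage", "holding_current",
    "elif_rheobase", "input_resistance", "IntegrationBlowUp",
    "InfeasibleHold", "lif_isi",
]

DEFAULT_DT = 0.01  # ms


class IntegrationBlowUp(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


class InfeasibleHold(ValueError):
    """Raised when no stable sub-threshold fixed point exists at the
    requested holding voltage."""


@dataclass(frozen=True)
class ELIFParams:
    """Exponential LIF parameters (defaults follow the reference cell)."""

    C: float = 170.0          # pF
    g_L: float = 25.0         # nS
    E_L: float = -75.0        # mV
    V_T: float = -60.0        # mV
    Delta_T: float = 15.0     # mV, spike slope factor
    V_r: float = -65.0        # mV, reset
    V_spike_cut: float = 0.0  # mV, divergence cutoff triggering reset
    g_shunt: float = 0.0      # nS, added linear conductance
    E_shunt: float = -75.0    # mV

    def __post_init__(self):
        if self.C <= 0 or self.g_L <= 0 or self.Delta_T <= 0:
            raise ValueError("C, g_L and Delta_T must be positive")
        if self.V_r >= self.V_spike_cut:
            raise ValueError("V_r must lie below V_spike_cut")

    def rhs_current(self, V):
        """Total membrane current (pA) entering dV/dt at DC input 0."""
        V = np.asarray(V, dtype=float)
        return (self.g_L * self.Delta_T * np.exp((V - self.V_T) / self.Delta_T)
                - self.g_L * (V - self.E_L)
                - self.g_shunt * (V - self.E_shunt))

    def small_signal_resistance(self, V: float) -> float:
        """Analytic small-signal resistance (MΩ) at voltage V."""
        g_eff = (self.g_L * (1.0 - math.exp((V - self.V_T) / self.Delta_T))
                 + self.g_shunt)
        return 1e3 / g_eff


@dataclass(frozen=True)
class PassiveLIFParams:
    """Standard LIF; g = 15 nS matches the eLIF input resistance at −75 mV."""

    C: float = 170.0
    g: float = 15.0
    E: float = -75.0
    V_thresh: float = -55.0
    V_r: float = -65.0
    g_shunt: float = 0.0
    E_shunt: float = -75.0

    def rhs_current(self, V):
        V = np.asarray(V, dtype=float)
        return -self.g * (V - self.E) - self.g_shunt * (V - self.E_shunt)


@dataclass(frozen=True)
class HHParams:
    """Reduced H-H model. Sigmoids are x_inf(V) = 1/(1+exp(-(V-half)/k)).

    The default persistent-Na+ activation (half 0 mV, slope 15 mV) gives the
    gradual sub-threshold rise in input resistance characteristic of the
    target cell class (roughly 60 → 140 MΩ between −85 and −65 mV at
    g_Nap = 150 nS) while keeping the spike-generating currents able to
    repolarize; see docs/methods.md for how this pair was settled.
    """

    C: float = 170.0
    g_Na: float = 170.0
    g_Nap: float = 150.0
    g_K: float = 90.0
    g_leak: float = 20.0
    E_Na: float = 50.0
    E_K: float = -90.0
    E_L: float = -80.0
    tau_n: float = 3.0
    act_m: Tuple[float, float] = (-30.0, 3.0)
    act_n: Tuple[float, float] = (-30.0, 3.0)
    act_p: Tuple[float, float] = (0.0, 15.0)
    g_inh: float = 0.0     # dynamic-clamp conductance (may be negative)
    E_inh: float = -75.0

    def m_inf(self, V):
        return _sigmoid(V, *self.act_m)

    def n_inf(self, V):
        return _sigmoid(V, *self.act_n)

    def p_inf(self, V):
        return _sigmoid(V, *self.act_p)

    def rhs_current(self, V, n=None):
        """Membrane current (pA) at voltage V with n at steady state unless
        given explicitly."""
        V = np.asarray(V, dtype=float)
        if n is None:
            n = self.n_inf(V)
        return -(self.g_Na * self.m_inf(V) * (1.0 - n) * (V - self.E_Na)
                 + self.g_Nap * self.p_inf(V) * (V - self.E_Na)
                 + self.g_K * n * (V - self.E_K)
                 + self.g_leak * (V - self.E_L)
                 + self.g_inh * (V - self.E_inh))


def _sigmoid(V, half, k):
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + np.exp(-(V - half) / k))


ModelParams = Union[ELIFParams, PassiveLIFParams, HHParams]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times in ms."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class SimulationTrace:
    """Voltage trace plus detected spikes from one simulation."""

    t: np.ndarray
    V: np.ndarray
    spikes: SpikeTrain
    dt: float
    aux: Optional[np.ndarray] = None       # H-H recovery variable n
    params_ref: Optional[ModelParams] = None
    seed: Optional[int] = None

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = {"t_ms": self.t, "V_mV": self.V}
        if self.aux is not None:
            cols["n"] = self.aux
        pd.DataFrame(cols).to_csv(path, index=False)


def _as_stim_array(stimulus, n_steps: int) -> np.ndarray:
    """Accepts a StimulusTrace, array, or scalar DC; returns a length-n array."""
    from .noise import StimulusTrace
    if isinstance(stimulus, StimulusTrace):
        arr = stimulus.samples()
    elif np.isscalar(stimulus):
        return np.full(n_steps, float(stimulus))
    else:
        arr = np.asarray(stimulus, dtype=float)
    if arr.size < n_steps:
        raise ValueError(
            f"stimulus covers {arr.size} samples but {n_steps} are required")
    return arr[:n_steps]


def simulate_model(params: ModelParams, stimulus, v0: float,
                   dt: float = DEFAULT_DT, duration: float = None,
                   record: bool = True, seed: Optional[int] = None
                   ) -> SimulationTrace:
    """Forward-Euler integration of one model.

    Parameters
    ----------
    params : model parameter set (selects the model equations).
    stimulus : StimulusTrace, array of injected current samples (pA), or a
        scalar DC value.
    v0 : initial voltage (mV).
    dt : Euler time step (ms); 0.01 ms is the reference value.
    duration : simulated time (ms). Defaults to the stimulus length.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(v0):
        raise ValueError("v0 must be finite")
    if duration is None:
        from .noise import StimulusTrace
        if isinstance(stimulus, StimulusTrace):
            duration = stimulus.duration
        elif np.isscalar(stimulus):
            raise ValueError("duration required with a scalar stimulus")
        else:
            duration = len(stimulus) * dt
    n_steps = int(round(duration / dt))
    I = _as_stim_array(stimulus, n_steps)
    t = np.arange(n_steps) * dt

    if isinstance(params, ELIFParams):
        V, sp_idx = elif_euler(v0, dt, I, params.C, params.g_L, params.E_L,
                               params.V_T, params.Delta_T, params.V_r,
                               params.V_spike_cut, params.g_shunt,
                               params.E_shunt)
        aux = None
        spikes = SpikeTrain(sp_idx * dt)
    elif isinstance(params, PassiveLIFParams):
        V, sp_idx = passive_lif_euler(v0, dt, I, params.C, params.g,
                                      params.E, params.V_thresh, params.V_r,
                                      params.g_shunt, params.E_shunt)
        aux = None
        spikes = SpikeTrain(sp_idx * dt)
    elif isinstance(params, HHParams):
        n0 = float(params.n_inf(v0))
        V, aux = hh_euler(v0, n0, dt, I, params.C, params.g_Na, params.g_Nap,
                          params.g_K, params.g_leak, params.E_Na, params.E_K,
                          params.E_L, params.tau_n,
                          params.act_m[0], params.act_m[1],
                          params.act_n[0], params.act_n[1],
                          params.act_p[0], params.act_p[1],
                          params.g_inh, params.E_inh)
        from .analysis import detect_spikes_array
        spikes = SpikeTrain(detect_spikes_array(V, dt))
    else:
        raise TypeError(f"unknown model parameter type {type(params)!r}")

    if not np.isfinite(V[-1]):
        bad = int(np.argmax(~np.isfinite(V)))
        raise IntegrationBlowUp(
            f"non-finite state at t = {bad * dt:.3f} ms")
    return SimulationTrace(t=t, V=V, spikes=spikes, dt=dt, aux=aux,
                           params_ref=params, seed=seed)


def steady_state_voltage(params: ModelParams, I_dc: float
                         ) -> Optional[float]:
    """Stable sub-threshold fixed point of the deterministic dynamics.

    Scans the deterministic right-hand side on a fine voltage grid below the
    spike region and returns the fixed point where total current crosses zero
    with negative slope (stable). Returns ``None`` when no stable
    sub-threshold fixed point exists (DC above rheobase).
    """
    v_hi = _subthreshold_ceiling(params)
    grid = np.linspace(-150.0, v_hi, 3001)
    f = params.rhs_current(grid) + I_dc
    sign_change = np.where(np.diff(np.sign(f)) != 0)[0]
    for i in sign_change:
        if f[i] > 0 and f[i + 1] < 0:  # downward crossing => stable
            return brentq(lambda v: float(params.rhs_current(v)) + I_dc,
                          grid[i], grid[i + 1], xtol=1e-10)
    return None


def _subthreshold_ceiling(params: ModelParams) -> float:
    if isinstance(params, PassiveLIFParams):
        return params.V_thresh - 1e-9
    if isinstance(params, ELIFParams):
        return params.V_spike_cut - 1.0
    return -20.0  # H-H: stay below the spike upstroke


def holding_current(params: ModelParams, V_hold: float) -> float:
    """DC current (pA) holding the deterministic model at V_hold.

    For the H-H model, gating variables are taken at their steady state.
    Raises :class:`InfeasibleHold` when the requested voltage is not a
    stable fixed point under that current (at or above the unstable branch).
    """
    I = -float(params.rhs_current(V_hold))
    v_ss = steady_state_voltage(params, I)
    if v_ss is None or abs(v_ss - V_hold) > 1e-6:
        raise InfeasibleHold(
            f"V_hold = {V_hold} mV is not a stable holding point")
    return I


def elif_rheobase(params: ELIFParams) -> float:
    """Closed-form deterministic rheobase of the eLIF (absolute DC, pA).

    The steady-state I-V curve I*(V) = (gL+gsh)(V−E_eff) − gL ΔT e^((V−VT)/ΔT)
    peaks at V* = V_T + ΔT ln((gL+gsh)/gL); sustained spiking occurs for DC
    strictly above I*(V*).
    """
    g_tot = params.g_L + params.g_shunt
    v_star = params.V_T + params.Delta_T * math.log(g_tot / params.g_L)
    return float(-params.rhs_current(v_star))


def input_resistance(params: ModelParams, V_hold: float, step: float = 5.0,
                     step_duration: float = 100.0) -> float:
    """Steady-state input resistance (MΩ) from a voltage-clamp step.

    Emulates the voltage-clamp protocol: R = ΔV / ΔI_ss where ΔI_ss is the
    change in steady-state holding current over a clamp step of ``step`` mV
    applied symmetrically about V_hold (gating at equilibrium); the centered
    step keeps the finite-step estimate close to the small-signal resistance
    at V_hold even where the I-V curve bends. With negative total
    conductance (unstable clamp region), the signed resistance is returned
    with a warning.
    """
    I0 = -float(params.rhs_current(V_hold - 0.5 * step))
    I1 = -float(params.rhs_current(V_hold + 0.5 * step))
    dI = I1 - I0
    if dI == 0.0:
        return math.inf
    R = 1e3 * step / dI  # mV/pA -> GΩ; x1000 -> MΩ
    if R < 0:
        warnings.warn("negative steady-state conductance in clamp region; "
                      "returning signed resistance", RuntimeWarning)
    return R


def lif_isi(params: PassiveLIFParams, I_dc: float) -> float:
    """Analytic inter-spike interval (ms) of the passive LIF at DC current.

    T = (C/g) ln((E + I/g − V_r) / (E + I/g − V_thresh)); requires the
    asymptote E + I/g to exceed V_thresh.
    """
    g = params.g + params.g_shunt
    v_inf = (params.g * params.E + params.g_shunt * params.E_shunt + I_dc) / g
    if v_inf <= params.V_thresh:
        raise ValueError("DC below threshold: no periodic firing")
    tau = params.C / g
    return tau * math.log((v_inf - params.V_r) / (v_inf - params.V_thresh))


# --- JSON (de)serialization -------------------------------------------------

_MODEL_KINDS = {"elif": ELIFParams, "passive_lif": PassiveLIFParams,
                "hh": HHParams}


def params_to_dict(params: ModelParams) -> dict:
    kind = {ELIFParams: "elif", PassiveLIFParams: "passive_lif",
            HHParams: "hh"}[type(params)]
    d = asdict(params)
    d["kind"] = kind
    return d


def params_from_dict(d: dict) -> ModelParams:
    d = dict(d)
    kind = d.pop("kind")
    cls = _MODEL_KINDS[kind]
    for key in ("act_m", "act_n", "act_p"):
        if key in d:
            d[key] = tuple(d[key])
    return cls(**d)


def params_to_json(params: ModelParams, path=None) -> str:
    s = json.dumps(params_to_dict(params), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def params_from_json(source: str) -> ModelParams:
    try:
        d = json.loads(source)
    except json.JSONDecodeError:
        with open(source) as fh:
            d = json.load(fh)
    return params_from_dict(d)
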