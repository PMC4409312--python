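"""Virtual experimental sessions: surrogate cells with the statistical
structure of the slice recordings this package models.

A virtual cohort is a set of conductance-based model "cells" (reduced H-H
with persistent Na+ by default) whose parameters are jittered cell-to-cell,
each with its own noise calibration to the target voltage-fluctuation SD at
−75 mV. The pharmacology and dynamic-clamp manipulations of the experiments
map directly onto model parameters:

* ``ttx_partial`` — partial block of persistent Na+ (g_Nap 150 → 75 nS);
* ``ttx_strong``  — full block (g_Nap = 0);
* ``gshunt_neg``  — dynamic-clamp negative conductance (g_inh = −5 nS,
  E_inh = −75 mV), deepening the endogenous negative slope conductance;
* ``gshunt_pos``  — positive shunt (g_inh = +15 nS, E_inh = −75 mV).

Each condition is re-run with a fresh noise calibration (the experimental
procedure holds the voltage-fluctuation SD constant across conditions) and
fresh trial seeds. Per-cell fluctuation-modulation metrics — stochastic
rheobase shift, spike-probability slope k, low-region f-I rate delta —
quantify how strongly fluctuations reshape the input-output relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .models import (HHParams, ModelParams, holding_current,
                     InfeasibleHold, IntegrationBlowUp)
from .noise import (calibrate_noise_coefficient, CalibrationError,
                    DEFAULT_TARGET_SD)

_m_errors = (InfeasibleHold, IntegrationBlowUp)
from .protocols import (ProtocolConfig, fi_protocol,
                        spike_probability_protocol,
                        step_transition_amplitude,
                        first_spike_trajectory, isi_trajectory,
                        trial_seed)
from .analysis import (fit_boltzmann, rheobase_from_steps,
                       fraction_above_midpoint, ahp_half_duration,
                       fit_linear_gain, MissingRheobase, FitFailure)

__all__ = ["VirtualCellSession", "make_virtual_cohort", "apply_condition",
           "condition_report", "cohort_metric_table", "CONDITIONS",
           "ConditionInstability"]

log = logging.getLogger(__name__)

CONDITIONS = ("control", "ttx_partial", "ttx_strong",
              "gshunt_neg", "gshunt_pos")

JITTERED_FIELDS = ("C", "g_Na", "g_Nap", "g_K", "g_leak")


class ConditionInstability(RuntimeError):
    pass


@dataclass
class VirtualCellSession:
    """One virtual cell under one condition, with its measured metrics."""

    cell_id: int
    params: ModelParams
    condition: str
    seed: int
    noise_coefficient: float = 0.0
    metrics: Dict[str, float] = field(default_factory=dict)
    curves: Dict[str, object] = field(default_factory=dict)


def _jittered_params(base: HHParams, jitter_cv: float,
                     rng: np.random.Generator) -> HHParams:
    """Log-normal multiplicative jitter (CV = jitter_cv) on conductances
    and capacitance."""
    if jitter_cv <= 0:
        return base
    sigma = np.sqrt(np.log(1.0 + jitter_cv ** 2))
    updates = {}
    for name in JITTERED_FIELDS:
        factor = float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))
        updates[name] = getattr(base, name) * factor
    return replace(base, **updates)


def apply_condition(params: ModelParams, condition: str,
                    ttx_partial_scale: float = 0.5,
                    scale_gna_with_ttx: bool = False) -> ModelParams:
    """Model parameters for an experimental condition.

    ``ttx_partial_scale`` is the residual fraction of g_Nap under partial
    block (default 0.5: 150 → 75 nS); ``scale_gna_with_ttx`` also scales
    the transient Na+ conductance by the same factor.
    """
    if condition == "control":
        return params
    if not isinstance(params, HHParams) and condition.startswith("ttx"):
        raise ValueError("TTX conditions require the conductance-based model")
    if condition == "ttx_partial":
        upd = {"g_Nap": params.g_Nap * ttx_partial_scale}
        if scale_gna_with_ttx:
            upd["g_Na"] = params.g_Na * ttx_partial_scale
        return replace(params, **upd)
    if condition == "ttx_strong":
        return replace(params, g_Nap=0.0)
    if condition == "gshunt_neg":
        out = replace(params, g_inh=-5.0, E_inh=-75.0)
    elif condition == "gshunt_pos":
        out = replace(params, g_inh=15.0, E_inh=-75.0)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    # negative conductance must not destabilize the resting state
    try:
        holding_current(out, -75.0)
    except Exception as exc:
        raise ConditionInstability(
            f"condition {condition}: no stable rest at -75 mV") from exc
    return out


def measure_session_metrics(session: VirtualCellSession,
                            repeats_pi: int = 15,
                            repeats_fi_noise: int = 10,
                            grid_pi: float = 10.0,
                            grid_fi: float = 25.0,
                            dt: float = 0.01,
                            include_trajectories: bool = False) -> None:
    """Run the protocol battery for one session and fill in its metrics.

    Metrics: ``det_transition`` (deterministic single-spike transition
    current on the 100 ms probability protocol), ``boltzmann_k`` and
    ``p02_shift`` (noisy probability curve), ``low_delta`` (fluctuation-
    induced rate change at the deterministic f-I rheobase), ``gain_det`` /
    ``gain_noise``; optionally ``frac_above_mid`` and ``ahp_half_ms``.
    """
    p = session.params
    seed = session.seed
    coeff = session.noise_coefficient

    # --- 100 ms spike-probability transition --------------------------------
    det_trans = step_transition_amplitude(p, step_duration=100.0,
                                          min_spikes=1, tol=2.0, dt=dt)
    amps = np.round(np.arange(det_trans - 120.0, det_trans + 90.0,
                              grid_pi), 6)
    cfg_pi = ProtocolConfig(step_amplitudes=amps, step_duration=100.0,
                            repeats=repeats_pi, noise_coefficient=coeff,
                            dt=dt, seed_base=seed + 1)
    pi_noise = spike_probability_protocol(p, cfg_pi)
    fit = fit_boltzmann(pi_noise.x, pi_noise.y)
    session.metrics["det_transition"] = det_trans
    session.metrics["boltzmann_k"] = fit.k
    session.metrics["p02_shift"] = det_trans - fit.P02_current
    session.curves["spike_probability"] = pi_noise

    # --- f-I low-region delta ----------------------------------------------
    rheo_fi = step_transition_amplitude(p, step_duration=1000.0,
                                        min_spikes=4, tol=2.0, dt=dt)
    fi_amps = np.arange(0.0, rheo_fi + 8 * grid_fi, grid_fi)
    cfg_det = ProtocolConfig(step_amplitudes=fi_amps, step_duration=1000.0,
                             dt=dt, seed_base=seed + 2)
    det = fi_protocol(p, cfg_det)
    try:
        rheo_grid = rheobase_from_steps(fi_amps,
                                        det.meta["spike_counts"][:, 0])
    except MissingRheobase:
        session.metrics["low_delta"] = np.nan
        return
    cfg_noise = ProtocolConfig(step_amplitudes=np.array([rheo_grid]),
                               step_duration=1000.0,
                               repeats=repeats_fi_noise,
                               noise_coefficient=coeff, dt=dt,
                               seed_base=seed + 3)
    noisy = fi_protocol(p, cfg_noise)
    det_rate = det.y[int(np.searchsorted(fi_amps, rheo_grid))]
    det_rate = 0.0 if np.isnan(det_rate) else det_rate
    session.metrics["low_delta"] = float(noisy.y[0] - det_rate)
    try:
        session.metrics["gain_det"] = fit_linear_gain(fi_amps, det.y).gain
    except FitFailure:
        session.metrics["gain_det"] = np.nan
    session.curves["fi_det"] = det

    if include_trajectories:
        cfg_t = ProtocolConfig(dt=dt, seed_base=seed + 4)
        traj = first_spike_trajectory(p, cfg_t, target_latency=50.0)
        session.metrics["frac_above_mid"] = fraction_above_midpoint(
            traj.t, traj.V_mean)
        cyc = isi_trajectory(p, cfg_t, target_rate=4.0)
        half = ahp_half_duration(cyc.t, cyc.V_mean,
                                 cyc.meta["threshold_V"])
        session.metrics["ahp_half_ms"] = np.nan if half is None else half


def make_virtual_cohort(n_cells: int, jitter_cv: float = 0.1,
                        seed: int = 0,
                        conditions: Sequence[str] = ("control",),
                        base_params: Optional[HHParams] = None,
                        target_sd: float = DEFAULT_TARGET_SD,
                        calib_seconds: float = 15.0,
                        max_redraws: int = 5,
                        run_protocols: bool = True,
                        **metric_kwargs) -> List[VirtualCellSession]:
    """Generate a seed-deterministic virtual cohort.

    Per cell: jitter the base parameters (log-normal, CV ``jitter_cv`` on
    conductances and C), calibrate the noise coefficient to ``target_sd``
    at −75 mV for every requested condition, and (optionally) run the
    protocol battery. Cells whose calibration fails are redrawn (logged),
    at most ``max_redraws`` times each.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    base = base_params if base_params is not None else HHParams()
    rng = np.random.default_rng(seed)
    sessions: List[VirtualCellSession] = []
    for cell in range(n_cells):
        for attempt in range(max_redraws + 1):
            params = _jittered_params(base, jitter_cv, rng)
            cell_seed = trial_seed(seed, 1_000 * cell + attempt)
            try:
                per_cond = []
                for cond in conditions:
                    cp = apply_condition(params, cond)
                    # 2 seeds put the SD estimate's own error near 2%, so
                    # the per-cell tolerance is opened up accordingly
                    coeff = calibrate_noise_coefficient(
                        cp, target_sd, calib_duration=calib_seconds,
                        n_seeds=2, tol=0.04, seed=cell_seed + 17)
                    per_cond.append((cond, cp, coeff))
                break
            except ((CalibrationError, ConditionInstability)
                    + _m_errors) as e:
                log.info("cell %d attempt %d redrawn: %s", cell, attempt, e)
                if attempt == max_redraws:
                    raise
        for k, (cond, cp, coeff) in enumerate(per_cond):
            s = VirtualCellSession(cell_id=cell, params=cp, condition=cond,
                                   seed=cell_seed + 1000 * (k + 1),
                                   noise_coefficient=coeff)
            if run_protocols:
                measure_session_metrics(s, **metric_kwargs)
            sessions.append(s)
    return sessions


def cohort_metric_table(sessions: Sequence[VirtualCellSession]):
    """Long-format DataFrame: one row per (cell, condition) with metrics."""
    import pandas as pd
    rows = []
    for s in sessions:
        row = {"cell_id": s.cell_id, "condition": s.condition,
               "noise_coefficient": s.noise_coefficient}
        row.update(s.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def condition_report(sessions: Sequence[VirtualCellSession]):
    """Per-condition mean ± SD summary of every measured metric."""
    df = cohort_metric_table(sessions)
    metric_cols = [c for c in df.columns
                   if c not in ("cell_id", "condition")]
    return df.groupby("condition")[metric_cols].agg(["mean", "std"])


def ordering_pvalues(sessions: Sequence[VirtualCellSession], metric: str,
                     condition_order: Sequence[str]):
    """One-sided paired p-values that ``metric`` increases along
    ``condition_order`` (adjacent pairs, per-cell pairing)."""
    from scipy.stats import ttest_rel
    df = cohort_metric_table(sessions).pivot(index="cell_id",
                                             columns="condition",
                                             values=metric)
    out = {}
    for a, b in zip(condition_order[:-1], condition_order[1:]):
        res = ttest_rel(df[b], df[a], alternative="greater")
        out[f"{a}<{b}"] = float(res.pvalue)
    return out
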