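# Methods

This note documents the models, the calibrated stochastic stimulus, the
protocols and statistics, the numerical choices, and the limits of what
the synthetic experiments can show. Units throughout: mV, ms, pA, nS, pF
(so pA/pF = mV/ms and nS·mV = pA).

## Models

**Exponential integrate-and-fire (eLIF).** Membrane voltage obeys

    C dV/dt = I_e + g_L Δ_T exp((V − V_T)/Δ_T) − g_L (V − E_L) − g_shunt (V − E_shunt)

with C = 170 pF, g_L = 25 nS, E_L = −75 mV, V_T = −60 mV, reset
V_r = −65 mV. The exponential term stands in for sub-threshold Na⁺
activation; the spike slope factor Δ_T sets how gradually input
resistance rises toward threshold. Δ_T = 15 mV reproduces the stellate-
cell phenotype (resistance roughly tripling between −85 and −65 mV,
near-linear spike approach, shallow power-law f-V curve); Δ_T = 2 mV is
the sharp-threshold comparator. Voltage diverges past V_T; a spike is
recorded and the state reset when V reaches 0 mV. The optional
`g_shunt`/`E_shunt` term is the linear "shunting inhibition" conductance
(15 nS at −75 mV in the increased-conductance condition; dynamic-clamp
style negative values are allowed).

The deterministic rheobase has the closed form
I* = max_V [(g_L+g_shunt)(V−E_eff) − g_L Δ_T e^((V−V_T)/Δ_T)], attained
at V* = V_T + Δ_T ln((g_L+g_shunt)/g_L). With the printed parameters and
Δ_T = 15, the two terms cancel at V_T and the absolute rheobase is
exactly 0 pA; since the cell is held at −75 mV by a bias current of
−137.95 pA, the rheobase *step amplitude* from the hold is ≈138 pA.

**Passive LIF.** A linear membrane (g = 15 nS, E = −75 mV, matching the
eLIF's −75 mV input resistance within 6%) with an artificial threshold
at −55 mV and the same reset. It isolates what a threshold without any
sub-threshold nonlinearity predicts.

**Reduced Hodgkin–Huxley model.** Two state variables (V, n):

    C dV/dt = I_e − g_Na m (1−n) (V−E_Na) − g_Nap p (V−E_Na)
              − g_K n (V−E_K) − g_leak (V−E_L) − g_inh (V−E_inh)
    dn/dt   = (n_∞(V) − n)/τ_n ,  h ≈ 1 − n,  m and p instantaneous

with C = 170 pF, τ_n = 3 ms, E_Na = 50, E_K = −90, E_L = −80 mV,
g_Na = 170, g_K = 90, g_Nap = 150, g_leak = 20 nS. All activation curves
are rising sigmoids x_∞(V) = 1/(1+exp(−(V−V_half)/k)); m and n use
(−30, 3). The K⁺ driving force is (V − E_K): the source equations print
(V − E_Na) in that term, which cannot repolarize and leaves E_K unused,
so it is treated as a typographical error.

*Persistent-Na⁺ activation.* The printed form of p is typographically
corrupted. Reading it by the same rendering convention as the printed m
and n sigmoids gives p = 1/(1+exp(V/−15)), i.e. V_half = 0 mV,
k = 15 mV, and this is the default. Two independent checks select the
same pair: (i) it produces the gradual sub-threshold resistance rise the
model exists to show (≈63 → 140 MΩ from −85 to −65 mV at
g_Nap = 150 nS, collapsing to a flat 50 MΩ at g_Nap = 0); (ii) any
substantially more hyperpolarized half-activation makes the persistent
current exceed the maximal K⁺-plus-leak current near −10 mV, creating a
stable depolarized fixed point — the model then fires once and locks up
(depolarization block), which contradicts the repetitive firing the
study requires. The pair is a package choice for a corrupted source
value, not a claim about the original authors' parameters.

**Integration.** Forward Euler at dt = 0.01 ms is the reference
integrator (the scheme the study specifies); a smaller dt is exposed for
convergence checks, and halving dt changes deterministic 1 s spike
counts by at most one spike. For the 1-D eLIF the Euler inter-spike
interval is verified against exact quadrature of the period integral
(agreement ~0.1%, tested at 2%). Integrators are numba-compiled; a 15 s
trace costs ~50 ms of wall time.

## Stochastic stimulus

Current fluctuations are low-pass filtered white noise built in the
frequency domain: amplitude A(f) = 1/(1 + f/f_cut) with f_cut = 100 Hz,
one independent uniform phase per bin, conjugate-symmetric spectrum,
inverse FFT. Amplitudes are deterministic and only phases random — the
simplest construction consistent with a frequency-domain recipe; its
marginal is asymptotically Gaussian. The series is constructed on a
0.1 ms grid (the 10 kHz rate at which the emulated dynamic-clamp rig
generates and delivers stimuli) and held sample-wise onto the 0.01 ms
integration grid. Noise is additive to the DC command; there is no
conductance noise.

The overall scale is linear in a dimensionless `coefficient`, normalized
so the time-domain SD is independent of record length (continuous-PSD
convention: variance ≈ coefficient² ∫A(f)² df). Absolute coefficient
values are therefore implementation-defined; all calibrated quantities
are expressed through the measured voltage SD, and the reference
coefficient ladder 90:140:280 is honored as ratios (reproducing the
2.3 : 3.6 : 7.5 mV SD ladder at −75 mV within 10%).

**Calibration.** The coefficient is titrated until the SD of sub-
threshold voltage at the −75 mV hold matches the target, measured over
15 s with spike-adjacent samples excluded (samples above −40 mV, plus
2 ms before and 10 ms after each spike, plus a 500 ms settling window).
Because the sub-threshold SD is nearly linear in the coefficient, a
scale-and-verify iteration converges in 2–3 passes (tolerance 2% with 3
seeds; the per-cell cohort calibration uses 2 seeds and a 4% tolerance,
matching the estimator's own noise floor). The default target is
2.41 mV — the *realized* SD of the recordings this stimulus emulates;
the nominal "≈2.5 mV" was measured there as 2.41 ± 0.1 mV, and the
reference model runs report an even slightly lower realized value
(2.3 mV). Reconstructions of the downstream fluctuation-modulation
numbers are consistent with this sub-nominal effective SD.

**Seeds.** One noise realization per trial; every trial draws a fresh
seed derived deterministically from the protocol's `seed_base`, so
repeats are independent and every output is bit-reproducible from
(config, seed).

## Protocols

All protocols hold the cell at −75 mV via a constant bias equal to the
holding current and report step amplitudes above that bias. Each trial
settles 1000 ms at the hold (fluctuations already on) before the step.

* **f-I**: 1 s steps on a 25 pA ladder; frequency = mean of the first
  three reciprocal ISIs (undefined below 4 spikes). With noise, the
  curve value is the mean over repeats with spike-deficient trials
  counted as 0 spikes/s — the convention that treats "failed to fire"
  as an output of 0 rather than discarding the trial. Rheobase = first
  ladder step with ≥4 spikes (median across repeats when noisy). Gain =
  OLS slope over all defined points.
* **Spike probability**: 100 ms steps on a 10 pA ladder, 15–25 repeats;
  P = fraction of steps with ≥1 spike. Noisy curves are fit with the
  rising Boltzmann P(I) = 1/(1+exp(−(I−I_half)/k)) (unweighted least
  squares; a binomially-weighted option exists but is off, matching the
  source analysis); the stochastic rheobase is the fitted current at
  P = 0.2.
* **f-V**: as f-I but 3 s steps (so the 4 spikes that define the lowest
  measurable rates, ~1.5 spikes/s, fit inside the step; deterministic
  first-3-ISI frequencies do not depend on step length). Mean voltage is
  taken over [first spike, fourth spike] over the *full* trajectory,
  including the spike upstroke to the 0 mV cutoff and the reset: the
  source computes "the mean during the same period" with no spike
  exclusion, and its two printed characterizations of the Δ_T = 15
  deterministic curve (exponent 1.78; ~10 mV span per 60 spikes/s) are
  reproduced only under the unclipped mean (clipping at −40 mV gives
  p ≈ 2.8 and a 4 mV span). A clip voltage remains config-exposed.
  The f-V curve is fit with f = a(V−V_c)^p + b, a ≥ 1, V_c ≤ min(V),
  multi-start least squares (V_c offsets × p ∈ {1, 1.5, 2}) because
  three-parameter power laws have abundant local minima.
* **Trajectories**: the first-spike trajectory is found by bisection on
  the step amplitude for a 50 ± 2 ms latency and truncated at the
  model's spike-initiation voltage (V_T for the eLIF, the artificial
  threshold for the LIF, −40 mV for the H-H upstroke); its shape metric
  is the fraction of time above the (start+end)/2 midpoint. The ISI
  cycle is extracted at a DC giving 4 ± 0.2 spikes/s steady firing,
  aligned at the AHP trough (the cycle's voltage minimum); its metric is
  the time from trough to the trough-threshold midpoint.
* **Interval-fraction probability**: with the cell firing periodically
  at ~4 Hz under DC alone, the full deterministic state at each cycle
  fraction seeds 1000 independent 50 ms noisy simulations; the curve is
  the fraction of trials with ≥1 spike per cycle phase.
* **Voltage-SD scan**: ≥15 s per DC level; mean and SD of sub-threshold
  voltage with the same spike-adjacent exclusions as calibration. The
  depolarized operating point for the SD-at-−68 mV measurement is found
  by titrating DC until the *measured* sub-threshold mean reaches
  −68 ± 0.15 mV.

## Virtual cohort

The cohort emulates an experimental session series with no external
data: n cells drawn from the reduced H-H model with log-normal jitter
(CV 0.1) on C and all maximal conductances — a generative choice; the
source reports only between-cell SEMs. The H-H model (not the eLIF) is
the "cell" because the experimental manipulations map directly onto its
parameters: partial TTX block scales g_Nap 150 → 75 nS (the residual
fraction is config-exposed and the transient Na⁺ can optionally scale
with it; by default it does not, matching the reference model
manipulation, which varied the persistent conductance alone), strong
block sets g_Nap = 0, and the dynamic-clamp conditions add
g_inh = −5 / +15 nS at E_inh = −75 mV. Each condition is recalibrated to
the target voltage SD (the experimental procedure held the SD constant
across conductance conditions) and re-run with fresh seeds. A cell whose
calibration fails or whose negative-conductance condition has no stable
rest is redrawn (logged, ≤5 redraws). Per-cell metrics: deterministic
single-spike transition current, Boltzmann k and P₀.₂ shift, low-region
f-I delta, deterministic gain, and optional trajectory metrics.
Orderings across conditions are assessed with one-sided paired t-tests
over cells.

What the cohort does *not* emulate: channel noise, electrode artifacts,
slow drift, spike-frequency adaptation, morphology, and any attempt to
fit individual recorded cells. Passing orderings therefore show that the
*mechanism* (sub-threshold negative slope conductance → weaker
fluctuation modulation) is robust to parameter heterogeneity — not that
the cohort is statistically indistinguishable from real recordings.

## Numerical and design choices

* Euler spike handling records the eLIF spike at the first sample where
  V ≥ 0 mV, before resetting; the stored sample at a spike index holds
  the post-reset voltage, and window-based analyses account for that.
* Steady states are located by sign-scanning the deterministic
  right-hand side on a fine grid and polishing the stable (downward)
  crossing with Brent's method; `holding_current` validates that the
  requested hold is such a stable point and raises otherwise.
* Input resistance applies the 5 mV clamp step symmetrically about the
  holding voltage (V ± 2.5 mV). The step direction is unstated in the
  source; the centered difference tracks the small-signal resistance —
  the quantity the resistance-voltage figures plot — far better where
  the I-V curve bends (at −65 mV on the Δ_T = 15 eLIF: centered
  ≈143 MΩ vs small-signal 141 MΩ, while an upward step gives 267 MΩ).
  As the step shrinks to 0.1 mV the measure converges to the analytic
  small-signal value within 1%.
* Shunt comparisons on the eLIF (the increased-conductance condition)
  deliver the *same* current fluctuations as baseline, per the source's
  procedure ("delivered the same current input fluctuations"); the
  cohort's dynamic-clamp conditions instead recalibrate per condition,
  matching the experimental SD bookkeeping there. Both paths exist in
  the API.
* Bisection tolerances: first-spike latency ±2 ms, steady rate
  ±0.2 spikes/s, rheobase searches ±0.5–2 pA — all an order below the
  effects measured.
* Problem sizes in the shipped drivers and acceptance path: ~30 DC
  levels × 3 s for f-V curves; 25 pA f-I ladders with 60–400 noise
  repeats at the rheobase step; 4–8 × 15 s stretches for SD measures;
  20-cell cohorts with 20 probability repeats per amplitude. These give
  standard errors several-fold smaller than the tolerances applied to
  them.

## Known limitations

* The Δ_T = 15 eLIF's fluctuation response at depolarized means is
  slightly hotter than the reference values: the sub-threshold voltage
  distribution at a −68 mV mean is right-skewed (excursions are
  amplified by the rising resistance and dwell near the slow region),
  and its raw SD stabilizes ≈11% above the reported 3.06 mV. If the
  reference SD was taken from a Gaussian description of the histogram,
  the skewed tail would be discounted; the package reports the raw SD.
* The low-region f-I delta for the Δ_T = 15 baseline converges to
  ≈5.1–5.5 spikes/s against a reported 4.2; single-realization noisy
  f-I curves (which the reference model figures appear to show) carry a
  ±2–3 spikes/s sampling error at this operating point, and the package
  reports many-seed means instead.
* Boltzmann fits on near-deterministic probability curves are flagged
  `degenerate` (transition narrower than the amplitude spacing); their
  k values index grid resolution, not biology.
* The eLIF-to-LIF limit is logarithmically slow (the divergence time
  above V_T decays like Δ_T ln(1/Δ_T)): at Δ_T = 0.1 mV the period still
  exceeds the analytic LIF formula by ~13% near rheobase. Tests assert
  the convergence trend and the exact quadrature oracle instead of a
  fixed small-Δ_T agreement.
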