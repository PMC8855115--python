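# Methods

This note documents the model as implemented, the choices made where the
design was genuinely open, the synthetic ground truth, and the problem sizes
used by the test suite and `scripts/acceptance.py`. It states no empirical
result that the tests and the acceptance script do not themselves compute.

## Model and assumptions

The population state is a pair of confluences (dimensionless fractions of
well area): proliferative cells `N_p` and senescent cells `N_s`. Untreated
growth is logistic with an Allee factor, `k_p·N·(N/θ + A)·(1 − N/θ)`; at low
density with `A = 1` this reduces to exponential growth at rate `k_p`. The
growth parameters (`k_p`, `θ`, `A`) are *fixed inputs* per cell line — in a
real study they come from a prior fit to untreated controls — and are never
co-estimated with the radiation parameters.

Radiation enters through three rate terms, summed over delivered fractions
(a fraction contributes only for `t ≥` its delivery time; the late-death
kernel `t_i·e^{−r t_i}` vanishes at delivery automatically):

| term | form | timescale | free parameters |
|---|---|---|---|
| acute death `k_ed` | `k_acute(D,N0)·f_DSB·tanh(s·f_DSB)` | hours–days (DSB repair) | `alpha_acute_N`, `k_acute_D` (full); `k_acute_N` (density-only) |
| accumulation death `k_ld` | `k_accum(D,N0)·t_i·e^{−r t_i}` | days–weeks (mitotic catastrophe) | `alpha_accum_N`, `k_accum_D`, `r` |
| senescent conversion | `k_ps(D_total)·N0·N_p` | whole course | one `k_ps` per total-dose arm |

`f_DSB(t, D) = exp(−k_repair(D)·t)` is the unrepaired double-strand-break
fraction; `k_repair` is piecewise-linearly interpolated from a measured
dose→rate table and clamped to the nearest endpoint outside the tabulated
2–16 Gy range (all per-fraction doses in use lie inside). Acute death acts as
direct removal (`−k_ed·N_p`); accumulation death reduces the effective
proliferation rate (`(k_p − k_ld)` in the growth term), which bounds its
effect when the population is far from growing. Senescent cells neither
divide nor die but share the carrying capacity.

Units follow dimensional consistency: `k_accum_D` is 1/(hr² Gy) because the
late-death kernel multiplies it by a time and a dose; `k_acute_D` is
1/(hr Gy); the `alpha_*` density scales are dimensionless; all other rates
are 1/hr.

Interpretation choices where the formulation was open:

- The growth product multiplies `N_p` only (only proliferative cells
  divide); the crowding and Allee factors use `N_p + N_s` (both occupy
  space).
- Model 3's late-death coefficient keeps the `·D` factor,
  `(alpha_accum_N·N0 + 1)·k_accum_D·D`, so that Model 3 is exactly the full
  model minus the acute dose dependence.
- The `tanh` gate on the acute term takes `g = tanh(s·f_DSB)` with
  sharpness `s = 1` by default. Because `f_DSB ∈ (0, 1]`, the gate is a
  smooth magnitude factor rather than a hard switch; the calibrated
  `k_acute` absorbs its scale, so `s` only affects continuity near fraction
  times. `s` is configurable (`gate_sharpness`).
- Daughter models 5 and 6 (late-death reductions) mirror the acute-death
  reductions by analogy: `k_accum_D·D` (dose-only) and `k_accum_N·N0`
  (density-only).

## Numerics

Simulation is fully explicit forward Euler, `dt = 0.01` hr by default, from
`N_p(0) = N0` (the measured confluence at time zero) and `N_s(0) = 0`. The
state is clipped at zero from below and clip events are logged. Output times
take the Euler grid point at or before each requested time (no
interpolation; `dt` is far below the 4–6 hr sampling interval). The
death-rate time courses are precomputed on the Euler grid, and the state
update runs in a numba-compiled kernel, so a 330-hr simulation costs ~1 ms.

An independent accuracy check, `simulate_reference`, integrates the same
rate functions with adaptive Runge–Kutta (`rtol = 1e-9`) piecewise between
fraction times (where the acute term switches on). Agreement is measured in
sup norm relative to the trajectory's maximum; the test suite requires
< 0.5% across 50 randomized parameterizations covering all eight models and
six schedules. Coarser steps (`dt` = 0.02–0.1) are used in some harnesses for
speed, always with the generator and the calibration sharing the same step.

## Calibration

All curves of a training set are fit together: one shared radiation
parameter vector, each curve simulated with its own measured `N0` and
schedule, `k_ps` selected by the curve's total dose. Residuals are plain
(model − data), concatenated in canonical replicate order; no weighting is
applied because no measurement-variance model is available. Minimization is
bounded trust-region least squares (`scipy.optimize.least_squares`,
`method="trf"`, bounds `[0, ∞)`): the classical Levenberg–Marquardt
algorithm does not support the nonnegativity bounds that the biological
definitions require. Multi-start is seeded: one fixed heuristic start plus
log-uniform draws (rates in `[1e-5, 1e-1]`, dimensionless scales in
`[1e-2, 1e2]`); tolerances default to `1e-10` with at most 2000 function
evaluations per start; the best final RSS wins. Fixed seed ⇒ bit-identical
results.

Uncertainty uses the standard nonlinear-regression machinery: covariance
`(JᵀJ)^{-1}·RSS/(m−p)` from the Jacobian at the optimum (pseudo-inverse with
a warning if `JᵀJ` is ill-conditioned), t-based confidence intervals with
`m − p` degrees of freedom, and an identifiability audit that reports
parameter pairs with |correlation| > 0.99. Cell lines are compared per
parameter with a two-sided z test on `(estimate, SE)` pairs.

Prediction intervals use the delta method: the gradient of the predicted
total confluence with respect to the free parameters is taken by central
finite differences (relative step `1e-6`; one-sided at the zero bound), and
the half-width is `t·sqrt(gᵀ·Cov·g)`. `interval="observation"` adds the
residual variance `RSS/(m−p)` and is the appropriate band for covering new
noisy measurements; the coverage test uses it.

## Model selection

Each of the eight candidates is calibrated on the same training set and
scored with `AICc = n·ln(RSS/n) + 2p + (2p² + 2p)/(n − p − 1)`. Following
the convention that one confluence curve is one sample, `n` defaults to the
curve count while RSS sums over every time point; `sample_count=
"observations"` switches `n` to the total point count. Akaike weights are
the standard `exp(−Δ/2)` normalization, so the lowest-AICc model gets the
largest weight; an alternative `relative-delta` normalization
(`exp((AICc−min)/min)`) is available behind a flag for comparison — note it
inverts the ranking and should not be used for selection. Ties resolve to
the model with fewer parameters.

Small-sample caveat: with the curve-count convention the AICc correction is
severe at desk scale — at `n = 18` curves the full model (p = 7) pays 5.6
more points than its 6-parameter daughters, an `e^{5.6/18} ≈ 1.4×` RSS
hurdle, whereas at several hundred curves the same margin is ~2 points
(< 1% RSS). Consequently the selection-recovery harness recovers daughters
2–8 reliably but attributes full-model (Model 1) data to Model 2: the
density scale of acute death is a subtle effect that cannot clear a 40% RSS
hurdle. This is a property of AICc at small n, not of the implementation,
and is left visible in the test suite rather than hidden.

## Synthetic data generator

The generator emulates the experimental design: two cell-line presets, six
daily-fraction schedules (2×8, 3×5.3, 4×4 Gy = 16 Gy; 2×10, 3×6.7, 4×5 Gy =
20 Gy, 24 hr apart, first fraction at t = 0), four seeding-confluence levels
log-spaced over 0.03–0.3 (a ~10× range, cycled so every condition spans it),
sampling every 4–6 hr to 330 hr, and multiplicative Gaussian noise truncated
at zero with CV 0.21 (the magnitude of typical segmentation error). The
75/25 split is stratified by cell line × schedule × density stratum
(below/above the condition's median seeding confluence).

Ground-truth parameter values are synthetic — chosen once to satisfy the
qualitative constraints of the modeled biology and not revisited:

- repair table `(2, 4, 8, 16) Gy → (0.115, 0.10, 0.085, 0.07)/hr`: slower
  repair at higher dose, > 80% of DSBs repaired within 24 hr at every
  per-fraction dose in use;
- late death dominates acute death (acute kills a minority early; the late
  term, peaking at `1/r ≈ 50` hr, drives the main decline);
- the "C6" preset is uniformly more radiosensitive than "9L" (larger death
  and conversion rates, similar `r`);
- noise-free trajectories show the expected morphology on weak schedules at
  low seeding: initial rise, post-treatment decline, late regrowth.

Per-replicate heterogeneity of the death rates (a CV on the coefficients)
and a media-change cell-loss artifact (persistent fractional drop every
120 hr) exist as options and are **off by default**: neither is quantified
by any measurement, and the recovery harnesses assume a shared truth.

What passing tests on these data do *not* show: robustness to replicate
heterogeneity, to non-Gaussian or autocorrelated segmentation error, to
media-change jumps, or to model misspecification — real microscopy data
carry all four.

## Identifiability under measurement noise

Because the initial condition of every simulation is the *measured*
confluence at t = 0, the 21% measurement noise enters the model inputs, not
just the outputs (an errors-in-variables effect). Parameters whose only
lever is the seeding-density dependence — `k_acute_N` and `alpha_accum_N` in
Model 3 — absorb this input noise and are biased well beyond their nominal
standard errors at study scale, while `k_accum_D`, `r` and the two `k_ps`
are recovered within a few percent to ~15%. The recovery tests therefore
assert 25% accuracy for the structurally identifiable quartet under study
conditions, and for all six parameters when the exact seeding density is
substituted for the noisy t = 0 measurement (which the suite also checks).

## Problem sizes

Chosen as the package's own desk-scale defaults: integrator oracle, 50
parameterizations (30 in the acceptance script); noise-free recovery, 24
curves at `dt = 0.01`; noisy recovery and validation, 96 curves (48 per cell
line, 8 replicates × 6 schedules) at `dt = 0.02` with a 75/25 split;
selection recovery, 18 curves per repetition, 20 repetitions per generating
model at 3% noise and `dt = 0.1` (generator and calibration share the step);
band coverage, 200 fresh validation curves. The demo pipeline
(`demo.yaml`) uses 6 replicates per condition at `dt = 0.05`.

## Known limitations

- `k_ps` is constant per total-dose arm; in reality conversion to
  senescence varies with time, dose per fraction and fraction number.
- Linear dose dependence of the death coefficients: no saturation, so
  extrapolation beyond ~4–10 Gy per fraction is unsupported.
- No replicate-level random effects; heterogeneity enters only through the
  optional generator CV, not the estimator.
- The delta-method band assumes local linearity in the parameters and
  homoscedastic residuals; under multiplicative noise its pooled coverage is
  correct on average but over-covers low-confluence points and under-covers
  the highest ones.
- Senescent cells are unobservable in the data; their compartment is
  identified only through its effect on total confluence.
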