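# Methods

## The cell model

`cardiopop` uses the O'Hara–Rudy (ORd, 2011) model of the undiseased human
ventricular myocyte, endocardial parameterization: 41 state variables
(membrane potential, 8 ionic concentrations across myoplasm, subspace and
sarcoplasmic reticulum, 29 gating variables, CaMKII-trap fraction and two
SR-release fluxes).  The equation set was transcribed by hand into
`cardiopop/_ord_kernel.py` from the published endocardial formulation
(geometry with the model's literal π = 3.14, C_m = 1 µF/cm², extracellular
Na/Ca/K of 140/1.8/5.4 mM, published initial state starting at V = −87 mV).
The transcription is validated three ways: the unstimulated model stays at
rest (|dV/dt| < 10⁻³ mV/ms after 10 s), paced behaviour matches an
independent scipy-BDF integration of the same right-hand side to within
~1 ms of APD80, and baseline biomarkers land on the model's known values
(APD80 ≈ 258 ms at 1000 ms BCL, diastolic Ca ≈ 85 nM).

Seven maximal conductances/fluxes are scalable, each exactly linear in its
multiplier at fixed state: G_Kr, G_Ks, G_K1, G_to, the L-type permeability
P_Ca (which also scales the channel's Na and K components), the Na/Ca
exchanger G_ncx (both myoplasmic and subspace branches), and J_up.

**J_up convention.** In the model's public encoding `J_up` is the single
net SR-uptake variable, (1−f)·J_up,np + f·J_up,CaMK − J_leak.  The SERCA
scaling here multiplies that net expression, i.e. the leak scales with the
pump.  This is the reading under which the package reproduces the published
failing-population medians simultaneously (CaTD80, CaTMax, DAPCaT and the
APD80 shift); scaling the uptake terms alone leaves the SR comparatively
overloaded and overshoots the failing DAPCaT and CaTD80 responses.

## Numerics

The production integrator is a compiled adaptive-step hybrid: every gating
variable relaxes exactly along its exponential toward its
voltage-dependent steady state (Rush–Larsen, with steady state and time
constant averaged over the step's two stage evaluations), while voltage,
concentrations and the CaMK trap advance with Heun's method.  The step size
is limited so |ΔV| ≤ 0.5 mV per step (dv_max), subspace and junctional-SR
calcium change ≤ 4% per step, and Δt ≤ 2 ms (1 ms on beats recorded for
output); all three limits are configuration (`SolverSettings`), and
`refined(k)` tightens them k-fold.  Tightening 10× moves baseline APD80 by
< 1 ms (converged for the biomarkers' purposes); the scipy BDF route
(rtol 10⁻⁶, atol 10⁻⁸) is retained for cross-checks and agrees to ~1 ms
APD80 and ~2% CaT amplitude.  One cell costs ≈ 0.2 s per 100 paces at
1000 ms BCL on one core.  Output for biomarker computation is Vm and Cai
resampled on a fixed 1 ms grid.

The stimulus (−80 µA/µF ≡ −80 µA/cm², 0.5 ms, onset at t = 0 of each pace)
is booked to the K⁺ balance for charge conservation.  Biomarkers are
interval-based, so the onset convention cancels out of every reported
quantity.

## Populations

Non-failing: all seven scalings independent uniform on [0.70, 1.30].
Failing: s_to, s_CaL, s_Kr, s_up uniform on [0.40, 1.00]; s_NaCa on
[1.00, 1.60]; s_Ks, s_K1 as non-failing.  These intervals are the study
conditions (mean mRNA changes of roughly ±60% around baseline with ±30%
natural variability); components are sampled independently because no
co-regulation information is available.  Sampling is driven by one named
`numpy` generator per population; the seed is recorded in every output
row.  Full-scale runs use 16384 cells/population over 11 BCLs; the desk
configuration uses 200 cells and 5 BCLs.

## Biomarkers and their conventions

Durations are measured from the **upstroke** — the time of maximum first
derivative on the 1 ms grid, sub-sample-refined by a quadratic fit through
the neighbouring slopes, ties broken to the earliest sample — to the first
fall below peak − f·amplitude after the peak, linearly interpolated
(f = 0.30, 0.80).  The amplitude baseline is the sample at the stimulus
onset of that beat, which is robust to slow diastolic drift.  DAPCaT uses
the same derivative-based upstroke for both signals; this convention
reproduces the published non-failing DAPCaT median essentially exactly.
Central values come from the final beat; the penultimate beat serves the
alternans rule (|ΔAPD80| ≥ 5 ms or |ΔCaTD80| ≥ 5 ms).  A beat counts as
captured when peak Vm > 0 mV and max dV/dt > 10 mV/ms; cells with a
non-captured beat (2:1 block, seen at fast rates in the failing
population's low-G_Kr corner) carry NaN biomarkers and are excluded from
medians, correlations and regressions, with exclusion counts reported.

At 300 ms BCL the failing population loses stable 1:1 capture mostly by
2:1 block rather than by sustained ≥5 ms APD alternans; analyses that
compare against aggregate "alternans" incidence at that rate should
consider the union of the two flags (see `alternans_counts`), since the
two rhythms occupy the same low-G_Kr parameter region.

## Regression

Per (condition, BCL, biomarker): rows surviving the exclusion rule are
fitted by SVD least squares (never normal-equations inversion) with an
explicit intercept; the response is mean-centred and scaled to unit SD.
Predictors are standardized by default, making coefficients "response SDs
per predictor SD" and directly comparable across parameters; the raw-scale
fit is available via `standardize_x=False`.  R² = 1 − SS_res/SS_tot.  Fits
with fewer than 10× the design-column count of usable rows are skipped with
a warning.  With mean-centred responses the intercept is numerically ~0 on
real runs.  A display-threshold helper reproduces the |β| > 0.2 reporting
rule.

## Surrogate data

`cardiopop.surrogate` generates analytic beat pairs — a 2 ms sinusoidal
upstroke (unambiguous steepest point) followed by a piecewise-linear
repolarization anchored exactly at the 30% and 80% recovery times — whose
biomarkers equal prescribed targets to within the 1 ms grid's interpolation
error, with optional per-parameter linear effects, Gaussian noise and
injected beat-to-beat alternation.  It emulates the *statistical* structure
the regression stage assumes (linear biomarker responses on uniform
scalings), not cardiac dynamics: no restitution, no bifurcations, no
mechanistic alternans.  Tests passing on surrogates therefore validate the
measurement and attribution machinery, while claims about the physiology
rest on the ODE model itself.

## Problem sizes and test design

The package's own test suite runs two reduced population studies chosen to
keep a full run in the tens of minutes on one core: 200 cells/condition
at 1500 and 1000 ms for median and regression checks, and 150
cells/condition through the full 11-step protocol for rate-dependent
checks.  Scaled comparisons against the study-size results use 5–15%
tolerances for medians and binomial 95% sampling intervals for alternans
proportions.  `scripts/acceptance.py` repeats the 1500 ms analysis from
scratch with a user seed.

## Known limitations

- Endocardial cells only; no epi/mid variants, no tissue coupling.
- Conductance scaling only — gating kinetics are never altered.
- The alternans/2:1-block boundary at 300 ms is solver- and
  history-sensitive; individual borderline cells can flip category under
  refinement, though population fractions are stable.
- Uniform, independent priors on the scalings; no co-regulation.
- The step protocol stores only the final two beats per rate; per-beat
  history beyond that is discarded by design.
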