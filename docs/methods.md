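# Methods

## Model

The simulator is phenomenological: it makes no claim about HPA-axis
mechanism. An individual's acute response is parameterized by seven
quantities — baseline B, onset delay T_on, time to maximum T_max,
maximum M, plateau duration D, return duration T_ret and recovery level
E — that fix five turning points,

    (0, B), (T_on, B), (T_max, M), (T_max + D, M), (T_max + D + T_ret, E).

This decomposition carries exactly the traits named in the empirical
literature (baseline, rate of initial increase = (M − B)/(T_max − T_on),
time of peak, maximum, plateau, return) with seven degrees of freedom.
Times are minutes since stressor onset; concentrations ng/µl.

**Population draw.** True phenotypes are drawn jointly from a 7-variate
normal with user-set means, SDs and correlation matrix. Parameters
flagged `log` (default: `max_value`) enter the joint normal on the
natural-log scale and are exponentiated afterwards, giving a
right-skewed marginal while the correlation applies on the sampling
scale. Draws violating the physiological constraints (B ≥ 0, E ≥ 0,
M ≥ B, 0 < T_on < T_max, D ≥ 0, T_ret > 0) are rejected and resampled
per individual (up to 1000 rounds); rejection preserves the joint shape
better than clamping but truncates extreme configurations — a rejection
rate above 50% raises an error suggesting re-specification. Correlation
matrices with tiny negative eigenvalues (> −1e−8, config rounding) are
repaired to the nearest PSD matrix; anything worse is rejected.

**Expression.** Each realized response mixes the individual's true
parameters with a *fresh* phenotype drawn from the same population
(hence the population covariance structure is preserved among expressed
parameters). Two blends are available, applied per parameter on its
sampling scale with weight w (fidelity):

* `convex` (default): θ_expr = w·θ_true + (1 − w)·θ_fresh. Literal
  blend; marginal variance shrinks by w² + (1 − w)², and the expressed
  trait's repeatability across events is w² / (w² + (1 − w)²).
* `variance_preserving`: θ_expr = µ + w(θ_true − µ) + √(1 − w²)(θ_fresh − µ).
  Marginal variance is exact for every w; repeatability is w².

Default fidelity is w = 0.35 for all parameters, chosen so the expressed
trait repeatability (≈ 0.22 under convex mixing) sits in the range
reported for stress-induced glucocorticoid measures in wild vertebrates
(roughly 0.2–0.4). Mixed parameter sets failing the physiological
constraints trigger a redraw of the fresh component.

**Curve realization.** Turning points are linearly interpolated onto the
integer minute grid 0..t_end (default 120 min, covering all scenario
windows plus recovery; values beyond the last turning point are held at
E to avoid extrapolation artifacts), then smoothed with locally weighted
linear regression (lowess, no robustness iterations) and clamped at 0.
The span (default 0.3) is interpreted as an *absolute* bandwidth of
span × 120 minutes rather than a fraction of the series length, so a
curve's interior is unchanged when the grid is extended; at the default
span the smoothed peak of a typical response is within 7% of M and its
argmax within 4–5 min of T_max (the smoother rounds the plateau
shoulders — intentional, matching the look of real time courses).

**Observation.** Sampling designs: `fixed` times shared by all
individuals; `uniform_random` times i.i.d. on a window per individual;
`weighted_normal` times from Normal(center, spread) truncated to
[0, t_end] by redraw (sampling weighted around the expected peak).
Measurements interpolate the smoothed curve linearly between grid
minutes and add Gaussian assay error (SD in ng/µl, default 1.0 in run
configs — a few percent of a typical maximum), clamped at a detection
floor (default 0). One master seed spawns independent child streams for
expression, sampling times, assay noise and fitness, so changing the
design does not perturb the expressed responses.

**Fitness.** fitness_j = Σ_i √v_i·z_ij + √v_u·ε_j, where z_ij is the
cohort z-score of true parameter i on its sampling scale, v_i the
user-set variance shares (Σ v_i + v_u = 1) and ε standard normal. With
uncorrelated parameters the asymptotic R² of fitness on true parameter
i equals v_i; because z-scores are taken on the sampling scale, that
guarantee applies to log-M for the log-scaled maximum (on the raw scale
lognormal curvature attenuates R² slightly, ≈ 0.76 instead of 0.80 at
log-SD 0.3).

## Repeatability estimators

The intraclass correlation is the one-way ANOVA ICC(1),
R = (MS_B − MS_W)/(MS_B + (k̄ − 1)·MS_W), with k̄ the harmonic-mean
number of events per individual; negative estimates are clamped to 0
with a warning, and a nonparametric bootstrap over individuals provides
optional CIs. This is transparent, dependency-light, and matches
mixed-model estimates for balanced designs (cross-checked against
pingouin's ICC(1,1) in the tests). AUC repeatability applies the ICC to
per-event trapezoidal areas, in ground (above zero) or increase (above
the first sample) mode, computed from the full stored event curve, from
the observed points only, or from the curve windowed to the observed
time range. Profile repeatability summarizes whole profiles over a
shared fixed time grid: V_w is the mean within-individual variance per
time point (averaged over times), V_a the between-individual variance
component of time-specific individual means (raw variance of means
minus V_w/k̄, clamped at 0), and the statistic is V_a/(V_a + V_w). The
subtraction matters: without it the ratio tends to 1/(1 + k̄), not 0,
when profiles are unrelated within individuals. The original
profile-repeatability formulation this stands in for is not fully
specified in the source literature available to us; treat it as a
documented variance-ratio summary rather than an exact replication.

## Scenario configurations

All scenarios emit tidy tables with per-cell child seeds and are exactly
reproducible from (arguments, seed).

* **Single-trait accuracy** (`scenario_peak_timing_sweep`): population
  with only M (linear scale, mean 25, SD swept 1–12 ng/µl) and T_max
  (mean 15/30/45 min, SD swept 1–20 min) varying; all other SDs 0.
  Moderate within-individual variability (w = 0.8) and small assay error
  (SD 1) held constant. n = 200 per cell, one event, observed at 30 min;
  outcome is R² of observed value on true M.
* **Speed–scope covariation** (`scenario_covariation`): T_max mean 30,
  corr(T_max, M) ∈ {−0.6, 0, 0.6} (negative = faster responders reach
  higher values), speed SD ∈ {2, 12} min, max SD ∈ {1, 10} ng/µl (M on
  the linear scale so the SDs are in concentration units); the noiseless
  expressed-curve value at each minute 0–35 is regressed on true T_max
  and true M separately (assay error omitted to isolate covariation
  effects). 50 replicates of 100 individuals by default.
* **Fitness detection** (`scenario_fitness_detection`): v(max) = 0.8,
  v_u = 0.2; log-scale SD of M ∈ {0.02, 0.5} (low/high between-individual
  variation), fidelity ∈ {0.9, 0.5} (low/high within-individual
  variation), n = 50 per population, 50 replicate populations, observed
  at 30 min with assay SD 1; records true and observed correlations and
  a two-sided p < 0.05 detection flag. The low setting 0.02 was
  calibrated so the four cells reproduce the qualitative detection
  pattern the scenario is designed to show (≈ all, ≈ all, ≈ half,
  ≈ none); at 0.1 detection saturates near 1 in every cell because the
  30-min measure retains substantial rank information about M even when
  its between-individual spread is modest.
* **Sampling-scheme design** (`scenario_sampling_schemes`): control
  T_max ~ N(30, 5), onset N(3, 1); treatment T_max ~ N(18, 5), onset
  N(1.8, 0.6) — 12 min (40%) faster with a steeper initial slope; equal
  log-M distributions. 20 individuals/group, one event, three samples
  each (120 data points), sampled from the *true* curves without assay
  error. Schemes: fixed 1/30/60, 1/15/30, 1/15/60; three uniform-random
  times on (1, 60); three times from N(32, 9) truncated to the valid
  window. Group curves are estimated by lowess (frac 0.4) on the pooled
  group points, evaluated on the 0–60 grid, with linear extrapolation
  along the boundary slope of the fitted curve outside the sampled range
  (the analogue of how a penalized-spline fit extends beyond its data;
  constant-hold extrapolation credits schemes with baseline information
  they never collected). Outcomes: mean absolute error against the true
  group-mean curve over 0–60 min, and the estimated vs true group
  difference in the time of the curve maximum.

## What the generator does and does not emulate

It reproduces the structure that matters for design questions: skewed
maxima, correlated response components, within-individual flexibility
with preserved covariance, irregular sampling times, additive assay
noise, and a fitness signal with known variance shares. It does **not**
model circadian baseline drift, habituation across repeated captures,
context-dependent reaction norms, negative-feedback dynamics,
multiplicative (CV-type) assay error, or unmeasured confounders linking
hormones and fitness — so a design that performs well here may still
fail in the field for reasons outside the model, and hormone–fitness
attenuation patterns in real data can run in either direction.

## Numerical choices and degenerate inputs

Trapezoidal AUC requires ≥ 2 strictly increasing times. Zero-SD sweep
cells report a missing R² with a warning (no variance to explain).
Repeatability with no variance at all returns NaN with a warning;
negative variance components clamp to 0 with a warning. The fixed
1/30/60 scheme yields tied lowess cluster means; peak-time estimates
then sit exactly on a sampled time. Problem sizes in the test suite
(e.g. a 3×4×4 sweep grid at n = 200, 10–50 scenario replicates) are the
package's default reduced sizes chosen to keep full runs in the
minutes range on one core; all are arguments, so larger studies just
pass larger values.

## Known limitations

* The seven-parameter decomposition is one consistent realization of the
  turning-point idea; alternative parameterizations (e.g. explicit slope
  parameters) would need a model change.
* The convex expression blend shrinks marginal variance (documented
  above); use `variance_preserving` when matching observed population
  variances across repeated events matters.
* Lowess group-curve estimates extrapolate linearly outside the sampled
  range; estimates more than ~10 min beyond the last sample are guesses
  and are flagged as such in the design-scenario discussion.
* ICC(1) assumes exchangeable events; systematic event order effects
  (habituation) would require a mixed model with event covariates.
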