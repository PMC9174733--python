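# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of `pentrack`.

## Data model

The unit of analysis is a *behaviour table*: one row per individual per
four-day observational time unit, holding five behaviours (total distance
travelled, core 50% area, total 95% area, site fidelity, feeder time) and
the covariates used as fixed effects (time unit, cohort, age at unit end,
mean pen temperature, breed, sex, weaning stage, health status). Tables
come either from raw positional streams via the preprocessing and metrics
stages, or directly from the metric-level generator.

## Preprocessing

Raw 1-Hz fixes are cleaned in a fixed order: exclusion windows (human
proximity, power cuts) → removal of out-of-pen fixes → moving-average
smoothing. The two filters are pure row deletions and commute (property
tested); smoothing runs last so that behaviours are computed from smoothed
data.

* **Smoothing** is a *centred* 10-s moving average. Centred (rather than
  trailing) preserves phase, which matters for step lengths; the window
  never bridges gaps longer than itself, so positions are not averaged
  across power cuts. At stream edges and next to gaps the window truncates.
* **Day boundaries** are local calendar midnights, not rolling 24-h
  windows. Units are consecutive blocks of 4 calendar days; a trailing
  partial unit is dropped; the first pen day can be discarded
  (habituation).
* **Sensor validation statistics**: CEP is the median (linear-interpolation
  percentile, type 7) distance of fixes from their mean — the radius of the
  circle centred on the mean fix containing half the fixes; DIST is the
  mean distance to the known ground-truth position. Under isotropic
  Gaussian noise with per-axis SD σ these converge to σ√(2 ln 2) ≈ 1.1774σ
  (Rayleigh median) and σ√(π/2) (Rayleigh mean); both limits are property
  tested against the estimators.

## Space-use metrics

* **Utilization distribution (UD).** Fixes are binned on a regular grid
  (default cell 0.1 m) over the pen plus a 0.5 m buffer, then convolved
  with a Gaussian kernel. The default bandwidth is the ad-hoc bivariate
  reference rule h = 0.5(sd_x + sd_y) n^(-1/6) per trajectory ("href"),
  overridable by an explicit bandwidth in metres. After smoothing, mass
  outside the buffered pen is removed and the UD renormalized to total
  mass 1 (enforced to 1e-9).
* **Isopleth areas** count whole cells: cells are sorted by density and
  accumulated until the requested level (0.50 core, 0.95 total) is first
  reached. No sub-cell interpolation — this keeps the estimator exactly
  oracle-checkable against a cumulative sum and guarantees
  core ≤ total and monotonicity in the level.
* **Site fidelity** is computed from daily UDs within a unit:
  H(p, q) = √(1 − Σ √(p q)) for each of the C(4,2) day pairs, averaged.
  Both orientations are exposed; the default *analysis variable* is the
  similarity 1 − H̄ (larger = more faithful to the same places), with the
  raw mean distance available via a flag, because the field's usage is
  ambiguous between the two. Days with under 50% of expected samples are
  excluded; a unit needs ≥ 2 eligible days, else the value is missing.
* **Feeder time** counts samples inside the (closed) feeder polygon and
  divides by the sampling rate; at 1 Hz a sample is a second.
* **Distance** sums Euclidean step lengths, skipping steps that span gaps
  longer than a threshold (default 10 s, equal to the smoothing window) so
  that data dropouts do not contribute phantom "teleport" steps. When
  analysing sub-Hz data the threshold must be raised accordingly.

## Repeatability (REML)

`fit_lmm_reml` fits the random-intercept model by REML via statsmodels
MixedLM, with treatment coding (references: first cohort/unit, female,
purebred dairy, not weaning, healthy) and the cohort × time-unit
interaction. Time unit is categorical, absorbing shared temporal trends.
Design decisions:

* Rank-deficient fixed designs (e.g. a cohort-by-unit covariate under a
  saturated interaction) are handled by dropping aliased columns via
  pivoted QR — the same behaviour R users get from lme4 — with a logged
  warning, never a silent failure.
* Negative variance estimates are truncated at zero and flagged singular.
* After the first optimizer converges, the fit is polished at a tight
  gradient tolerance (gtol 1e-10) when the likelihood surface allows; on
  balanced one-way designs the estimates then agree with the closed-form
  ANOVA estimators (V_e = MSW, V_ind = (MSB − MSW)/n) to ≤ 1e-6 relative
  error (property tested).
* **Uncertainty** is a seeded parametric bootstrap (default 1000
  replicates): simulate from the fitted model, refit, percentile interval.
  The interval method is a package choice; a coverage study at truth
  R = 0.5 (20 × 6 design, 200 outer replicates) sits at the nominal 95%
  level. For an intercept-only spec on balanced data the bootstrap refits
  use the closed-form balanced REML estimator, which the property test
  above certifies equal to the iterative fit.

## Location-scale models (DHGLM)

The univariate model puts a random intercept in the mean *and* in the log
residual SD; individual residual SDs are therefore lognormal and the
population coefficient of variation in predictability is
CVp = √(exp(ω²_ID) − 1) — the standard lognormal CV, applied draw-wise to
the posterior of ω²_ID and summarized by the posterior mean and a central
95% credible interval. (Note CVp(ω² = ln 2) = 1.)

The multivariate model stacks T z-scored behaviours (full-sample mean/SD),
gives each individual 2T random effects with one full covariance matrix
(type–type = behavioural syndromes, type–rIIV = personality–predictability
correlations, rIIV–rIIV = predictability syndromes) and models a full
residual cross-trait correlation matrix, so correlations are separated at
the among- and within-individual levels. The univariate `re_structure`
flag offers both independent and correlated (α, α_d) structures, since
either convention is defensible; the correlated structure is what the
type–rIIV correlations require.

### Sampler

Sampling is Metropolis-within-Gibbs, written for this model family:

* conjugate Gaussian updates for mean fixed effects and behavioural types
  (per trait, conditioning on the other traits' standardized residuals
  through the residual correlation matrix);
* vectorized adaptive random-walk Metropolis for the dispersion random
  effects (one proposal per individual per sweep, per-individual step
  sizes adapted to 0.44 acceptance during burn-in only, so detailed
  balance holds after burn-in) and for the dispersion fixed effects;
* conjugate inverse-Wishart (or inverse-gamma, for the independent
  structure) updates of the random-effect covariance;
* random-walk Metropolis on residual correlation entries with
  positive-definiteness enforced by rejection (a uniform prior over PD
  correlation matrices);
* an interweaved *recentering* move: an exact conditional draw of a joint
  translation between each intercept fixed effect and the mean of its
  random-effect vector. This is likelihood-invariant and removes the slow
  β₀ ↔ mean(α) random walk of the centred parameterization (intercept ESS
  improves by an order of magnitude).

**Priors.** N(0, 10²) on all fixed effects; IW(K + 1, 0.02 I) on the K × K
random-effect covariance. The IW degrees of freedom give uniform marginal
correlations (equivalent to LKJ(1) on the correlations); the scale is
deliberately small because an inverse-Wishart has vanishing density at
zero — a larger scale audibly props variance components away from 0 and
inflates CVp when individuals do not actually differ in predictability.
With 60 individuals the data dominate this prior for any non-degenerate
variance. All hyperparameters are exposed (`PriorSpec`) so calibration
studies can use proper moderate priors.

**Settings.** Defaults follow the four-chain protocol (10 000 iterations,
burn-in 5000, thinning 10 univariate; burn-in 6000, thinning 4
multivariate). The draw count satisfies
chains × (n_iter − burn_in)/thin exactly. The sampler is seeded (one seed,
per-chain substreams) and bit-reproducible.

**Diagnostics.** Split-R̂ and ESS per stored parameter (via arviz), plus a
Raftery–Lewis run-length estimate (2.5% quantile, ±0.005 at 95%)
implemented from the two-state Markov chain construction. Parameters with
R̂ > 1.05 (configurable) are flagged non-converged in the output rather
than silently passed.

**Validation.** The sampler is checked four independent ways: recovery of
generator truths (including the realized, not just nominal, random-effect
variances); agreement of the variance ratio with REML when the dispersion
submodel is flat; null recovery (ω² = 0 → CVp near 0; zero correlations →
intervals covering 0); and a reduced simulation-based calibration study
(20 × 6 design, parameters drawn from proper priors, posterior ranks of
ω²_ID checked for gross non-uniformity).

## Synthetic data

**Metric-level generator.** Draws behaviour tables exactly from the model
above: random effects (all trait intercepts, then all trait dispersion
effects) from a scaled multivariate normal with a user correlation matrix
(validated symmetric PD, unit diagonal); residuals
e_ij ~ N(0, exp(η₀ + α_d,j)²). The configured `v_res` is the *mean*
residual variance: η₀ = ½ log v_res − ω², so E[σ_j²] = v_res exactly. The
optional covariate design reproduces the study layout (four cohorts of
14/14/16/16 calves with the observed sex/breed frequencies, ages,
per-cohort temperature series, weaning schedule, sporadic health events);
all covariate effects default to zero so the variance-component truth is
exact, and can be switched on for adjustment studies.

**Trajectory-level generator.** Per individual: a two-dimensional
Ornstein–Uhlenbeck walk (exact discretization) around a random home
centre, reflected at the pen walls. The study design it emulates is a
6 m × 10 m pen sampled at 1 Hz with a 1.5 m × 3 m feeder zone. Feeder
visits arrive as a daily Poisson process with lognormal durations; during
a visit the animal dwells inside the feeder polygon, and outside visits
the feeder polygon is treated as an obstacle (it is a machine), which also
makes "no visits → no feeder samples" exact. Day-level lognormal
multipliers on the OU parameters (default log-SD 0.2) create genuine
residual intra-individual variability in the unit-level metrics — the
trajectory-level analogue of α_d. Isotropic Gaussian positional noise
(default SD 0.127 m, giving CEP ≈ 0.15 m) and bursty gaps (default 3.14%
of samples in exponential bursts, mean 10 min) are applied last. One
master seed spawns per-individual substreams, so adding individuals never
perturbs existing ones. Pre-noise positions are guaranteed inside the pen
and carried in the trajectory metadata for validation.

What the trajectory generator does *not* emulate: social interactions and
displacement at the feeder, diurnal activity rhythms, collar-orientation
artefacts, and spatially correlated UWB error near walls. Passing tests on
synthetic trajectories therefore certify the computational pipeline, not
the biology of any particular pen.

## Problem sizes

The test suite and the acceptance script run everything at the study's
design size where it matters for the statistics (60 individuals × 12
units) and scale down what does not: trajectory fixtures use a few
individuals at reduced sampling rates (the metrics are rate-aware), MCMC
runs use 2–4 chains of 2000–3000 iterations (posterior means of the
reported quantities are seed-noise-dominated well before that), the
bootstrap coverage study uses a 20 × 6 design, and the calibration study
uses 12–20 generator draws. These sizes are package defaults for automated
verification; the model-fitting defaults remain the full four-chain
protocol above.

## Known limitations

* The dispersion submodel assumes lognormal individual SDs; heavy-tailed
  residual families are out of scope.
* No random slopes, no autocorrelated (e.g. AR(1)) residuals within
  individuals; the four-day unit length is relied on to dampen
  autocorrelation.
* The UD estimator is a plain kernel density; autocorrelation-aware
  home-range estimators are out of scope.
* Small posterior attenuation of extreme correlations (|ρ| near 1) is
  expected from the uniform-correlation prior at J = 60.
* CVp is bounded away from zero at finite sample sizes: with n units per
  individual the likelihood cannot distinguish ω² below ≈ 1/(2n), so even
  under a true ω² = 0 the posterior mean CVp settles near 0.1 for n = 12.
  This is a property of the model class, not of the sampler.
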