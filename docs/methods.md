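# Methods

This note documents the statistical models behind `epfsit`, the choices
made where the methodology was genuinely open, and what the synthetic
data do and do not establish about real bioassays.

## Time–mortality model and LT50

Cumulative mortality in a treatment is modelled as a binomial GLM of the
proportion dead by day *t* on *t* (logit link by default, probit and
log-day available), fitted by IRLS. The median lethal time is
LT50 = −β₀/β₁ and its variance follows from the delta method,

Var(LT50) = (1/β₁²)·[Var(β₀) + LT50²·Var(β₁) + 2·LT50·Cov(β₀, β₁)].

Replicates are pooled by default (summed deaths over summed initial
counts per day), since the convention in this assay family is a single
LT50 ± SE per strain; per-replicate fits are available.

**Coefficient covariance.** Cumulative counts on successive days
re-count the same flies, so they are serially dependent; the naive
independent-binomial covariance a plain GLM reports is anti-conservative
(in simulation its 2-SE interval covered the generating LT50 in only
81/100 runs at the default design). The default covariance is therefore
a model-based sandwich A⁻¹BA⁻¹ in which B uses the exact covariance of
cumulative counts under the fitted model,
Cov(y_t, y_s) = m·[F(min(t,s)) − F(t)F(s)] within a replicate cohort.
This restores nominal coverage (96/100) while leaving the point estimate
and the delta-method formula unchanged. `se_method="glm"` selects the
naive covariance.

Abbott's correction, 100·(T − C)/(100 − C) floored at 0, is applied to
cumulative percentages when a control series exists; LT50s are fitted on
raw mortality by default (whether published LT50s used corrected or raw
mortality is generally unstated, so both paths exist).

The SIT-compatibility window is [10, 20] days inclusive: below it the
fungus kills sterile males before they can mate and compete; above it
the kill rate contributes too little. The window is configurable.

## Thermal performance models

Plate-level absolute growth rates (mm/day) are OLS slopes of the
mean-of-four-quadrants radius on day. Rates are fitted at the plate
level (4 plates × 6 temperatures = 24 observations per strain) rather
than as per-temperature means; this preserves replicate information and
is the natural unit of the radial-growth assay.

Three rate–temperature models are supported:

- linear: μ = a + bT;
- Lactin-1, in the polynomial form μ = a(T−Tmin)²(Tmax−T) with
  parameters (a, Tmin, Tmax). This matches the parameterisation used in
  the cardinal-estimate tables this package targets; the classical
  exponential Lactin-1 is available as the separate model name
  `lactin1_classical` and is deliberately not an alias of `lactin1`;
- CTMI (cardinal temperature model with inflection) with parameters
  (μopt, Tmin, Topt, Tmax), constrained to Tmin < Topt < Tmax. The
  response is μopt at Topt and 0 at both cardinal extremes — an
  algebraic identity used as a primary correctness check.

Outside [Tmin, Tmax] the nonlinear models evaluate to 0, and all models
are floored at 0 (negative radial growth is not meaningful); fitting
residuals use this clamped form.

**Fitting.** Weighted least squares via trust-region reflective
minimisation, with ordering constraints enforced by a log-gap
reparameterisation (Tmin, ln(Topt−Tmin), ln(Tmax−Topt); amplitude on a
log scale), so every iterate is admissible. Starts form a fixed grid:
Tmin offsets {−15, −5, 0} °C from the coldest observed temperature, Tmax
offsets {0, +5, +15} °C above the warmest, Topt over the observed
temperatures, amplitude from the largest observed rate. The best
residual sum of squares over all starts wins, ties broken by start
order, making the fit deterministic. Convergence tolerances are 1e-14
(x, f, g); weights default to 1, inverse-variance-per-temperature
weights can be supplied.

**Comparison.** AIC uses the Gaussian-RSS form n·ln(RSS/n) + 2(k+1),
counting the error variance as a parameter — reproducible without
assuming any further likelihood structure. Pseudo-R² = 1 − RSS/TSS and
adj-R² = 1 − (1−R²)(n−1)/(n−k−1). Selection ranks by ascending AIC;
|ΔAIC| < 2 counts as a tie and is broken by adj-R²; exact remaining ties
are flagged for the Vuong test. The Vuong statistic uses per-observation
Gaussian log-likelihood differences with each model's ML variance
(RSS/n) and ω̂ estimated with ddof = 0 (Vuong's original form);
z = Σmᵢ/(√n·ω̂), two-sided normal p, and ω̂ < 1e-12 is reported as
indistinguishable with z = 0.

The cardinal summary reports the literal min/max over strains for the
overall thermal range and the [min, max] of Topt; excluding outlying
strains (e.g. a physically implausible negative Tmin) is left to the
caller, since any such rule is a judgement call, not arithmetic.

## Survival analysis

Kaplan–Meier product-limit estimation over distinct event times with
Greenwood variance; censored-only groups give a flat curve at 1.
Administrative censoring at the end of the 15-day observation window is
recorded as event = 0 at day 15. The Mantel-Cox log-rank test pools
event times across G groups, treats ties by the standard shared-risk-set
hypergeometric rule, and computes χ² = (O−E)ᵀV⁻¹(O−E) over G−1 groups
(pseudo-inverse for near-singular V), df = G−1. The donor-vs-receiver
LT50 comparison uses the pooled-variance Student t-test by default
(consistent with df = nA+nB−2 reporting in 4-vs-4 designs); Welch is a
flag.

## Shared statistics

One-way ANOVA and the t machinery delegate to scipy. Tukey HSD uses the
Tukey–Kramer statistic with studentized-range tail probabilities from
scipy's numerically integrated distribution (absolute tolerance well
below 1e-6); with two groups it reduces exactly to the pooled t-test
(q = |t|√2). Compact letters use the insert-and-absorb algorithm with
columns ordered by first member, so output is deterministic and the
defining invariant — two groups share a letter iff their adjusted p ≥ α
— holds exactly.

The in-package IRLS GLM (binomial-logit/probit, Poisson-log) iterates to
a relative deviance tolerance of 1e-8 (max 100 iterations) with
step-halving, so the deviance trace is non-increasing by construction.
Covariance is the inverse of the final weighted information matrix.
Separation is flagged when the deviance is numerically zero with extreme
linear predictors (|η| > 20) or coefficients are extreme (>1e4);
rank-deficient designs are reported, not silently dropped. The GLM
defaults are binomial-logit for proportions and Poisson-log for counts.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
validated:

- **Mortality**: per fly, a continuous logistic death time
  X ~ Logistic(lt50, 1/slope) observed at the daily inspection
  (ceil(X), clamped to ≥ 1), competing with a geometric background
  process — earliest death wins. P(death ≤ t) is then exactly the
  logistic the analysis GLM assumes, so recovery experiments test
  estimation, not model mismatch. Defaults: 30 flies × 3 replicates,
  15-day horizon, background hazard 0.5%/day (no published control
  level exists; this is a plausible healthy-colony rate, chosen once).
  Parameter-recovery experiments set the background hazard to 0 because
  they target the fungal process itself; the background is a separate
  nuisance handled by Abbott's correction in the analysis path.
- **Radial growth**: radius = plug + rate(T)·day + N(0, σ), truncated to
  the physical plate [4 mm plug, 45 mm edge]; noise default σ = 0.1 mm
  (5% of the default μopt of 2 mm/day). Series are not forced monotone:
  measurement noise can make a reading smaller than the previous day's.
- **Germination**: Binomial(100, p(T)) per coverslip, 4 coverslips × 4
  plates, with any user-supplied unimodal p(T) clipped to [0, 1].
- **Survival**: geometric death days (the discrete-time constant-hazard
  analogue), censored at day 15.
- **Conidia loads**: lognormal multiplicative noise (default sd 0.4 on
  the log scale) around initial_load·retention^day; loads are positive
  and right-skewed, and the log-linear retention slope recovers
  ln(retention) exactly at zero noise.

All generators are bit-reproducible for a fixed seed (numpy
`default_rng`).

What passing these simulations does **not** show: real bioassays have
between-replicate heterogeneity beyond binomial noise, interval-censored
death times coarser than the daily grid assumption, temperature
fluctuation within incubators, and non-logistic mortality kinetics. The
simulation results establish correctness of the estimators under their
assumed models, not robustness to those violations.

## Problem sizes used in validation

Recovery and calibration suites run at the design sizes of the assays
they emulate: CTMI recovery and model selection over 200 simulated data
sets of 24 plate-rates each; LT50 coverage over 100 simulated 90-fly
bioassays; log-rank type-I calibration over 2000 two-group null
simulations (n = 30/group). Noiseless runs check exactness (cardinals to
1e-3 °C, RSS < 1e-10); noisy runs check frequency properties (≥90%
cardinal recovery within 1.5 °C, ≥95% 2-SE coverage, rejection rate in
[0.038, 0.062]).

## Degenerate inputs and numerical conventions

- Abbott correction is undefined at 100% control mortality (error) and
  floored at 0 (no negative corrected mortality).
- A germination mean of exactly 80% fails the viability gate (strict >).
- CTMI evaluation raises on a degenerate denominator (|den| < 1e-12 at
  an in-range temperature) and on non-ordered cardinal parameters.
- AIC is −∞ for an exactly zero RSS (a numerically perfect fit
  dominates any comparison).
- Zero conidia loads are excluded from log-decay fits with their count
  reported; no pseudo-count is added.
- The classification window is inclusive at both ends: LT50 = 10 and
  LT50 = 20 are compatible.

## Known limitations

- The time–mortality GLM treats the recorded death day as exact;
  genuinely interval-censored likelihoods are out of scope.
- No dose–response over conidia concentration (assays use a single dry
  conidia exposure), no Cox regression or competing risks, no
  humidity/UV covariates in the thermal models, and no extrapolation of
  fitted thermal responses outside [Tmin, Tmax].
- Published cardinal-estimate tables in this literature can be
  internally inconsistent (e.g. impossible R² entries); the package
  validates its CTMI implementation through the μopt-at-Topt identity
  and simulation recovery rather than by refitting unpublished data.
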