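# Methods

## Data model

The unit of analysis is a complete person-round panel: every person is
observed in rounds `1..T` (no gaps; incomplete persons are an error unless
explicitly dropped), with a binary Medicaid indicator, time-varying
employment, self-rated health (1 = good/very good/excellent) and household
income, baseline demographics, and four non-negative integer utilization
counts per round (ER visits, office/outpatient visits, inpatient
discharges, prescription fills).  `T` is a dataset property rather than a
constant: two-year panels are usually described as five interview rounds,
but six periods per person is equally coherent with published
person/observation counts, and nothing downstream depends on the choice.

A *transition* is an adjacent-round change of the Medicaid indicator.
Since the sample is defined by enrollment in at least one round, persons
with zero transitions are continuously enrolled; the analysis groups are
none / single / multiple transitions, entering regressions as two
indicators.  Direction of transitions is deliberately not modeled.

Derived covariates: within-person means of employment and health are taken
over all `T` rounds (also for the dynamic specification — the full history
maximizes the information in the Mundlak proxy); income enters as the
ratio to the grand person-round mean, so its grand mean is exactly 1;
round fixed effects are dummies with the first *modeled* round as
reference (round 1 for static fits, round 2 for dynamic); age is baseline
age and treated as time-constant.

## Likelihoods

With `λ_it = exp(x_it'β)` and a multiplicative unit-mean gamma effect
`c_i ~ Gamma(θ, θ)` (variance `1/θ`), the person-level marginal
log-likelihood is closed-form:

    Σ_t [y_t log λ_t − log y_t!] + lnΓ(θ + S_y) − lnΓ(θ)
      + θ log θ − (θ + S_y) log(θ + S_λ),

with `S_y = Σ_t y_t`, `S_λ = Σ_t λ_t`.  As `θ → ∞` this reduces to the
pooled Poisson log-likelihood (no heterogeneity).

The alternative log-normal effect (`log c_i = σ u_i`, `u_i ~ N(0,1)`) has
no closed form; it is evaluated by *adaptive* Gauss–Hermite quadrature:
nodes are recentered at the per-person posterior mode of `u` (found by a
one-dimensional Newton iteration on a strictly concave function) and
rescaled by the posterior curvature.  Plain Gauss–Hermite centered at the
prior loses several digits when large person totals shift the posterior
away from zero; the adaptive rule keeps worst-case error below 1e−8 at 32
nodes on the instance sizes tested.  `σ = 0` returns the pooled Poisson
exactly; one node gives the Laplace approximation.

Gamma mixing is the default (closed form, and the conventional
random-effects Poisson panel estimator); the normal family is a
sensitivity axis, since applied work rarely states the mixing law.

## Estimation

Parameters are `(β, log θ)` or `(β, log σ)` — the log transform enforces
positivity without constraints.  Starting values: a pooled Poisson Newton
(IRLS) fit for `β`; a method-of-moments dispersion start from the
overdispersion of person totals, `1/θ̂ = Σ[(S_y−S_λ)² − S_y] / Σ S_λ²`,
clipped to `[0.02, 1000]` on the variance scale.  Optimization is BFGS
with analytic gradients, followed by Newton refinement using the
finite-difference Hessian of the analytic gradient; convergence is
declared when the Newton decrement (expected log-likelihood gain of a full
step) falls below `1e−8·(1+|ℓ|)`.  Everything is deterministic given the
data; two fits of the same frame are bitwise identical.  Non-convergence
is reported in the result and propagated as a warning into rendered
tables, never silently.

Standard errors come from the inverse observed information (numerical
Hessian at the optimum); the mixing parameter's SE is delta-method
transformed from the log scale.  IRRs are `exp(β̂)` exactly; table cells
show `IRR(SE_IRR)` with `SE_IRR = IRR·SE_β` (delta method) and stars at
p<0.10 / 0.05 / 0.01 from two-sided normal tests.  The design matrix is
rank-checked (pivoted QR on scaled columns) before fitting, and collinear
columns are named in the error.

Degenerate inputs: `rate ≤ 0`, `θ ≤ 0`, mismatched lengths and
non-finite rates are domain errors; the log-pmf uses `xlogy`/`gammaln`
and is stable for counts to at least 1e4.

## Synthetic data generator

The generator produces panels whose every feature the estimators rely on
is controllable and known:

- **Enrollment** is a first-order Markov chain
  (`p_start_enrolled = 0.743`, `p_stay_enrolled = 0.954`,
  `p_stay_unenrolled = 0.532` by default) with two couplings: current
  employment shifts the log-odds of exiting and re-entering coverage
  (default ±1.1), and standardized age raises both staying probabilities
  (default 0.5) — employment-tested eligibility churns, disability-based
  eligibility does not.  Persons never enrolled are redrawn (the sample is
  Medicaid-ever).  The defaults were calibrated once, by simulation, to
  the observed two-year group mix of roughly 53% / 30% / 17%
  none/single/multiple transitions, and frozen.
- **Covariates**: employment and health follow stationary binary Markov
  chains parameterized by marginal probability and persistence
  (`P(x_t=1|x_{t−1}) = r·x_{t−1} + (1−r)·π`; defaults π=0.31/0.68,
  r=0.85); income is log-normal with a person effect and an employment
  boost, scaled to mean 1; baseline demographics follow simple laws with
  Medicaid-adult-like proportions.
- **Individual effects**:
  `c_i = exp(g_e(ē_i − π_e) + g_h(h̄_i − π_h)) · a_i` with `a_i` unit-mean
  gamma.  The systematic part is *linear in the within-person means*, so
  the CRE specification is correctly specified on these data while the
  base specification omits a relevant regressor that correlates with the
  transition indicators (through the employment–enrollment coupling).
  This is exactly the contrast the estimators exist to expose.
- **Outcomes**: round-1 counts are drawn from the model without the lag
  term (including `c_i`, so the initial condition is genuinely
  non-exogenous); later rounds recursively with log-mean
  `x'β + log c_i + ρ·h(y_{t−1})`.  A guard aborts if any log-mean exceeds
  20, which indicates an explosive configuration.
- One seed drives named substreams (statics, time-varying, enrollment,
  outcomes), so adding an outcome never perturbs the enrollment draws;
  outcomes are generated in sorted-name order so configuration files and
  in-memory configs draw identically.

Default outcome coefficient vectors give per-round means near observed
adult-Medicaid magnitudes (≈0.14 ER visits, ≈2.6 office visits, ≈0.08
discharges, ≈6.5 fills per round); intercepts were calibrated once to
those targets and frozen.

What the generator does **not** emulate: survey weighting and variance
strata, attrition and item nonresponse, overlapping calendar panels,
reporting error in enrollment, and any directionality of transitions.
Passing recovery tests therefore show the estimators work when their
assumptions (and the stated deviations) hold — not that observational
estimates from real survey data are unbiased.

## Designed validation studies

Two replicated experiments (in `medchurn.studies`) drive the deepest
tests.  Replication seeds derive from one master seed via `SeedSequence`.

**Static CRE bias study.**  Individual effects load strongly on employment
and health history (`g_e = 1.0`, `g_h = −0.8`, θ=2) and churn is strongly
employment-linked (log-odds shifts ±1.6).  Across replications the base
static specification overstates the multiple-transition coefficient by
≈+0.18 on the log scale, while the CRE specification's mean error is
within ±0.02 of zero and beats the base specification in well over 80% of
replications.

**Dynamic recovery study.**  True state dependence ρ=0.05 per lagged
count, identity `h`.  With identity `h`, the dynamic process is explosive
once `ρ·E[y]` approaches 1 in the upper tail of the effects, so this study
lowers the outcome intercept (per-round mean ≈0.4) and tightens the
mixing tail (θ=4); this keeps the prescribed ρ stable by design.  The
dynamic specification recovers ρ to within one Monte-Carlo SD of a single
replication's estimate, and its initial-condition coefficient is positive
(mean z ≈ 10) in essentially every replication.

A known, intentional property of this design: because round-1 counts are
generated *with* `c_i`, the estimator's `exp(ψ·y_1)` conditioning is an
approximation — the true `E[c | y_1]` is gamma-posterior-shaped
(`∝ (θ+y_1)/(θ+λ_1 m_i)`), not log-linear in `y_1`.  This leaves a small
asymptotic attenuation of ρ̂ (≈−0.005 at these settings, stable in N) and
a mild upward shift of θ̂.  It is the realistic price of a non-exogenous
initial condition, which is the scenario the estimator is for; a data
generating process drawing `c_i` log-linear in `y_1` would make the
estimator exactly specified and the bias vanish, at the cost of assuming
away the problem.

## Descriptive tests

Group comparisons use a Welch (unequal-variance) t-test for continuous
variables and a pooled two-proportion z-test for binary ones, both
two-sided, each transition group against the no-transition group.
Published tables of this kind rarely name their tests; these choices are
standard but should not be assumed to match any particular source, and
per-round comparisons ignore within-person clustering (as such tables
typically do).  Under identical-group nulls the empirical size at α=0.05
is within [0.035, 0.065] over 2000 simulated datasets.  Utilization is
summarized per person-round (not per person-year), matching the scale of
per-round means like 0.14 ER visits.

## Problem sizes

The test-suite runs the recovery studies at 200 replications of N=3000,
T=6, and the acceptance script at 60 replications of N=2000; both sizes
give Monte-Carlo SEs an order of magnitude below the effects being
measured.  Likelihood oracle checks use 200 randomized instances with
T ≤ 6 and counts ≤ 20 against max-shifted adaptive quadrature
(`scipy.integrate.quad` applied to `exp(logjoint − max)`), which is
accurate to ~1e−11 — naive quadrature of the raw integrand underflows on
small-probability instances.

## Known limitations

- Negative-binomial, zero-inflated, GEE and fixed-effects Poisson
  alternatives are out of scope by design.
- SEs are model-based (observed information); no sandwich/robust option
  is wired to the tables yet, and no survey weights are supported.
- The dynamic estimator's initial-condition device is the standard
  single-regressor form; richer conditioning sets (interactions with
  round, initial covariates) are not implemented.
- Income normalization is by the grand person-round mean; person-level
  normalization is a documented alternative the schema permits but the
  frames do not expose.
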