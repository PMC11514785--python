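# Methods

## Model

Cross-sectional SW-CRT data are analysed with a fixed-effects GLM: for
individual `k = 1..n_ij` in cluster `i = 1..I` during period
`j = 1..J`,

    g(E[Y_ijk]) = δ Z_ij + φ_j + α_i,

with `g = logit` for binary outcomes (Bernoulli likelihood) and
`g = log` for counts (Poisson likelihood).  The coefficient vector is
ordered `β = (δ, φ_2..φ_J, α_1..α_I)` with no global intercept and
`φ_1 = 0`, so the intervention-effect variance is always the (1,1)
element of the inverse information.  The model assumes a constant
intervention effect, period effects shared by all clusters, and
exchangeable individuals within cluster-periods; it makes no assumption
about how cluster effects relate to other covariates, which is exactly
why it tolerates time-invariant cluster-level confounding.

## Variance theory

With `V = diag(v(μ))`, `v(μ) = μ(1−μ)` (logistic) or `μ` (Poisson), the
large-sample covariance is `(X'VX)⁻¹`.  Partitioning the information
around the intervention column,

    X'VX = [[A, B'], [B, D]],   Var(δ̂) = (A − B' D⁻¹ B)⁻¹.

Because all covariates are cell-constant, `swfe.variance` assembles
`X'VX` exactly at cluster-period level (`Σ n_ij v(μ_ij) x_ij x_ij'`)
from true or fitted parameters — no individual expansion, no Monte
Carlo.  Three data configurations of a trial with unexposed clusters
are compared: `exposed_only` (drop them), `plus_first_period` (keep
only their first period), `full` (keep everything).  The first two give
identical `Var(δ̂)` — a single retained period adds a block-diagonal
information contribution that cancels out of the Schur complement — and
`full` is strictly smaller whenever an unexposed cluster has positive
size in ≥ 2 periods, because `D_full − D_first` is positive
semi-definite and the Loewner ordering is inverted by matrix inversion.
The package verifies these facts numerically (they are also checked on
hundreds of random designs in the test suite), rather than symbolically.

An always-exposed cluster is equivalent to an unexposed one: shifting
the extra cluster's intercept by `−δ` equalizes each cell's linear
predictor, hence its weight total, under the two roles, and the
resulting variances agree to machine precision.
`always_exposed_equivalence` asserts the matched-weight case and merely
*reports* the unmatched case (the two differ when `δ ≠ 0` because the
weights differ), since the general condition is a weight-matching
statement.

Numerics: Schur complements use a Cholesky factorization of `D`
(`scipy.linalg.cho_factor`), never an explicit inverse — the explicit
full inverse exists only inside test oracles.  Equality is asserted at
1e-9 relative, strictness at a 1e-12 relative gap, PSD at a minimum
eigenvalue ≥ −1e-8; these bands reflect double-precision accumulation
over a few hundred cells.  Clusters with zero individuals in every
retained cell are dropped from the analytic layout (their fixed effect
carries no information); the data-fitting path instead raises, since a
dataset claiming such a cluster is malformed.

## Estimation

`swfe.glm.fit` maximizes the likelihood by Newton–Raphson (IRLS):
convergence when the largest absolute score component falls below 1e-8,
cap of 100 iterations, initialization at `β = 0` except cluster effects
at the link-transformed cluster mean clamped away from the boundaries
(probabilities to [0.02, 0.98], rates to ≥ 0.02).  Step-halving (up to
30 halvings) keeps the log-likelihood non-decreasing, and the recorded
`loglik_path` lets tests assert that invariant.  The fitting loop is
written in-house because the score/information machinery *is* the
object of study here — the covariance must agree element-wise with the
analytic Schur-complement path, the log-likelihood trajectory and
separation behaviour are part of the contract — while an established
GLM implementation serves as an independent cross-check in the tests.

Complete separation (a binary cluster with all-0 or all-1 outcomes
drives its fixed effect to ±∞) is detected by a coefficient exceeding
20 on the link scale or a weight underflowing 1e-12, and reported as
`diagnosis="separation"` with `converged=False` instead of raising;
rank-deficient model matrices raise, naming the collinear columns from
QR pivots.  The Poisson log-likelihood includes the `−ln(y!)` constant
so AIC/BIC are comparable across nested models.  Wald intervals use the
exact normal quantile (1.959964 at 95%), which reproduces published
3-decimal interval arithmetic.

The period-homogeneity check augments the model with unexposed-cluster
× period dummies (period 1 as reference, columns with no observations
dropped) and reports which model AIC and BIC favour.  It is a
diagnostic, not a gate: including an unexposed cluster is only sensible
when its secular trend matches the exposed clusters'.

## Simulator

The generator mirrors the analysis model but treats cluster effects as
latent draws: `α_i ~ Normal(μ_α, τ²)` on the link scale, linear secular
trend `φ_j = 0.1·(j−1)` (so `φ_1 = 0`), Bernoulli or Poisson outcomes
independent given `(α, n)`.  The normal law is a choice — the
moment-only specification `(μ_α, τ²)` does not name a distribution —
but it is the one consistent with the latent-scale ICC conversions
used throughout:

    binary:  ρ = τ² / (τ² + π²/3)          (logistic-normal)
    count:   ρ = τ² / (τ² + ln(1 + e^{−μ_α}))   (Poisson-lognormal)

Cluster-period sizes arise in two stages: a per-cluster average
`n_i ~ Gamma(shape k, scale θ=1)` drawn **once** and reused across
periods (sizes are cluster-level, so period sizes within a cluster are
positively correlated), then `n_ij ~ Poisson(n_i)`.  Defaults encode
the study conditions: baseline prevalence 0.30 (`μ_α = ln(0.30/0.70)`
binary, `ln 0.30` count), effect sizes `δ ∈ {0, ln 1.25}` (binary) and
`{0, ln 0.80}` (count), ICC ∈ {0.01, 0.05, 0.1} via the conversions
above, mean cluster sizes `E[n_i] ∈ {30, 100, 300}`.

Randomness follows a counter-based substream contract:
`SeedSequence(seed, spawn_key=(scenario_id, replicate))`, so any
replicate of any scenario is independently reproducible and
order-independent.

The synthetic case-study fixture (`make_case_study_fixture`) emulates
only the *shape* of a real 5-cluster, 5-period palliative-care trial
whose data are not public: 4 stepped + 1 unexposed cluster, binary
outcomes, ≈ 3460 individuals, event rate near 0.3, a small positive
effect (δ = 0.05).  It shares none of the real data's covariate
structure, case-mix, or temporal idiosyncrasies, so analyses of it
demonstrate the pipeline and the qualitative SE ordering — not the
published estimates.  More generally, passing tests on simulated data
show correctness *under the generator's assumptions* (common period
effects, exchangeable individuals, non-informative cluster sizes); they
cannot certify behaviour under model misspecification.

## Simulation study and metrics

`swfe.study` runs the full factorial — 3 exposed-cluster counts ×
5 unexposed counts × 2 effects × 3 ICCs × 3 sizes = 270 scenarios per
family — with per-replicate simulate → expand → fit → test cycles.
Metrics over the `S` replicates follow the standard definitions: abs
bias `mean(δ̂) − δ`; rel bias `100·abs/δ` (non-null only); precision
`1/mean(V̂ar(δ̂))`; power / type-I error as the one-sided 0.05 Wald
rejection rate (`H0: δ ≤ 0` for binary, `δ ≥ 0` for count, strict
`p < 0.05`); coverage of the 95% CI; RMSE `sqrt(mean((δ̂−δ)²))`; Monte
Carlo SE as the sample SD of the `δ̂`.  These satisfy
`RMSE² = MC_SE²·(S−1)/S + bias²` identically, which the tests use as an
internal consistency check.  Non-converged replicates are excluded from
all averages, counted in `n_converged`, and a scenario with > 5%
exclusions is flagged; at the default settings separation is
vanishingly rare.

Problem sizes: the default replicate count is `S = 2000`; the bundled
calibration studies (test suite and acceptance script) use `S = 500`,
which gives binomial Monte-Carlo SEs of ≈ 1.0 percentage point on a 5%
rate and ≈ 1.0 point on 95% coverage — tight enough to detect material
miscalibration while keeping each study to a few thousand model fits.
Acceptance bands are stated in those binomial SEs (2 SE for the type-I
rate, 3 SE for coverage), not tuned constants.

## Design choices that were genuinely open

- **Clusters per step.** Balanced wedges require the exposed-cluster
  count to divide evenly over the `J−1` steps; unbalanced counts are an
  explicit error rather than a silent convention.  The
  `precision_gain_curve` "randomized" mode, which must add arbitrary
  numbers of clusters to a wedge, assigns extras to steps round-robin
  from the earliest step.
- **Homogeneity-check reference.** Interaction dummies use period 1 as
  the reference so the interaction model nests the base model with
  exactly `J−1` extra parameters per unexposed cluster (fewer when
  cells are empty).
- **Analytic vs fitted weights.** Variance functions accept either true
  parameters (design-stage) or `β̂` (post-fit); the caller chooses
  explicitly, never a silent mix.

## Limitations

- No mixed-effects comparators (random-intercept or nested
  correlation-structure models), no overdispersion/quasi-likelihood,
  no small-sample degrees-of-freedom corrections, no exact logistic
  regression.
- Incomplete/staircase layouts, transition periods, and closed-cohort
  (repeated-measures) sampling are out of scope; the simulator is
  cross-sectional with non-informative cluster sizes.
- The between-cluster variance is not estimated from fixed-effects
  fits; ICC conversion utilities work on supplied `τ²`/ρ values only.
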