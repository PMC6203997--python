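# Methods

## Model form and estimation

All models are specified in RAM form over named variables (observed first,
then latent): a directed-path matrix **A** (`A[i, j]` is the path j → i), a
symmetric variance/covariance matrix **S**, and a filter **F** selecting
the observed block. The implied covariance is Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ.
Matrix entries are `Fixed(value)` or `Free(label)`; entries sharing a label
share one parameter, which is how equality constraints are imposed — never
by post-hoc averaging of separate estimates.

Estimation minimizes the normal-theory discrepancy
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p over the free parameters. Only the
covariance structure is modeled; means are saturated and drop out of the
likelihood, so models can be fitted from printed summary statistics alone.

**Sample-size convention.** Descriptive summaries use the n−1 (sample)
denominator throughout. The fitting engine by default rescales the input
covariance by (n−1)/n and reports χ² = n·F_ML(θ̂) — the convention of
widely used commercial SEM software, chosen so that results line up with
the bulk of the applied dyadic literature. `n_mult="n-1"` switches to the
Wishart convention (χ² = (n−1)·F_ML on the unrescaled matrix) for
cross-checking against other packages. Unstandardized path estimates are
identical under both conventions; χ² and variance estimates differ by the
factor (n−1)/n.

**Optimizer.** Quasi-Newton (BFGS) minimization with finite-difference
gradients, run in a rescaled parameter space (each coordinate divided by
max(1, |start|)) so that path coefficients of order 1 and variances of
order 10–40 present comparable curvature; without this, convergence on
constrained models is an order of magnitude slower. Start values come from
per-outcome moment equations: normal equations for recursive outcomes,
instrumental-moment equations (instruments = exogenous variables) for
feedback outcomes, averaged across slots sharing a label; free
variance/covariance slots then start at the entries of (I−A)S(I−A)ᵀ, which
is already the MLE for saturated models. Latent slots use
cross-indicator heuristics (the covariance of two unit-loading indicators
estimates the latent variance). Convergence requires a scaled-gradient
norm below 1e−6; up to 5 jittered restarts are attempted, after which the
best point is returned with a warning. Implied matrices outside the
positive-definite domain during the search are handled by a smooth
penalty, not an exception.

**Standard errors and tests.** The parameter covariance is the
pseudo-inverse of the central-difference Hessian of (N/2)·F_ML at θ̂, with
an ill-conditioning warning above condition number 1e10. z ratios use
two-sided standard-normal p-values (not t), matching common SEM software.
Variance parameters are unconstrained in sign during optimization;
negative fitted variances are reported with a Heywood-case warning rather
than failing. χ²-difference tests require a strictly positive df
difference and clip differences in (−1e−6, 0) to zero.

**Fit indices.** The baseline for CFI/TLI is the independence model (free
variances, all covariances fixed to zero), whose MLE is diag(S) in closed
form. This is an approximation to the baselines of some commercial
packages; for well-fitting models (χ² < df), the reported 1.000 values are
insensitive to the choice. TLI is reported capped at 1 with the raw value
retained. RMSEA = sqrt(max(χ²−df, 0)/(df·n)) and is 0 by convention
(flagged `rmsea_defined=False`) for saturated models. SRMR averages
squared standardized residuals over all p(p+1)/2 unique elements including
the diagonal.

## The three dyadic frameworks

With design order (x₁, x₂, y₁, y₂):

- **APIM**: paths x₁→y₁ (a₁), x₂→y₂ (a₂), x₂→y₁ (p₁₂), x₁→y₂ (p₂₁); free
  exogenous variances + covariance and residual variances + covariance.
  10 parameters, df = 0 (saturated). Variants `actor_equal`,
  `partner_equal`, `both_equal` tie the respective labels (df = 1, 1, 2).
- **MIM**: actor paths plus reciprocal y₁⇄y₂ feedback paths; nonrecursive,
  just-identified (df = 0). Stability requires the feedback-loop product
  away from 1 (singular (I−A) raises a dedicated error naming the loop).
  Indirect effects actorᵢ × feedback use first-order delta-method SEs from
  the estimated parameter covariance.
- **CFM**: latent predictor and outcome, all four loadings fixed to 1,
  latent regression b, free latent variance φ and latent residual ψ, four
  indicator residual variances and two within-person residual covariances:
  9 parameters, df = 1. Unit loadings are the default identification
  (matching standard practice for dyad-level constructs); a
  `fixed_variance` parameterization (φ = 1 with shared tau-equivalent
  loadings per construct, df = 0) is available behind a flag for scale
  sensitivity checks. Explained couple-level variance is
  R² = b²φ/(b²φ + ψ), reported as a percentage, with negative ψ clipped
  (and warned) in the ratio.

## Hypothesis suite

Seven standard questions: (1) actor effects, (2) partner effects, (3)/(4)
gender equality of actor/partner effects, (5) feedback effects, (6) gender
equality of feedback, (7) couple-level effect. Effects are judged by
two-sided z tests at configurable α (default 0.05); equality hypotheses by
χ²-difference tests of the tied variant against the basic model. H2 is
judged on the pooled partner effect from the equality-constrained model,
with both per-direction tests reported in the detail block: when the two
directions are similar in size, the pooled test is the better-powered
summary and a single nonsignificant direction does not by itself refute an
overall partner effect. H5 is supported if either feedback direction is
significant.

## Synthetic data and validation

The generator draws i.i.d. multivariate-normal dyads from the covariance
implied by a chosen framework and population parameter values — Gaussian
only, since the point is validating the ML estimator under its own
assumption, not robustness testing. APIM/CFM populations use the same RAM
identity as the engine; the MIM uses its reduced form
Y = (I−B)⁻¹(ΓX + e), and the two routes agree to machine precision (a
cross-check in the test suite). Positive-definiteness and feedback
stability (|b₁₂·b₂₁| < 1) are validated at specification time.

Default population values echo the packaged example's scale: predictor
variances ≈ 18–20, outcome residual variances ≈ 34–40, actor effects
≈ −0.45 (APIM) / −0.37 (MIM), feedback 0.57/0.33, and the fitted CFM
values (φ = 3.95, b = −1.44, ψ = 10.3). Recovery experiments therefore
probe the estimator in a realistic questionnaire regime rather than a
unit-variance idealization. What the generator does *not* emulate:
discreteness and boundedness of sum scores, non-normal tails, missing
data, or heterogeneous dyads — passing recovery tests demonstrates
estimator correctness under the model's assumptions, not robustness to
their violation.

Seeding: one master seed; each replicate uses a child generator keyed by
(grid-cell index, replicate index) through `numpy`'s `SeedSequence` spawn
keys, so replicates are mutually independent and any replicate is
reproducible in isolation. Simulated tables are bit-for-bit reproducible
for a fixed seed and package version.

Problem sizes used by the validation suite: deterministic refits of the
packaged 141-couple moments (fractions of a second per model); recovery at
n = 1000 with 500 replicates per framework; equality-test size at n = 1000
with 1000 replicates; moment-convergence checks at n = 50 000.

## Known limitations and numerical notes

- Missing data are handled by listwise deletion per analysis;
  full-information ML is out of scope.
- Printed correlations carry 3 decimals, so refits of published tables
  agree with the original raw-data analyses only to that input precision
  (differences up to ~0.01 on paths and ~0.02 on small χ² values are
  expected and observed).
- The CFM latent regression is a ratio-type estimand; when the couple-level
  variance share is small (as in the packaged example's regime), its
  finite-sample bias at n = 1000 is of order 0.02 on a parameter of
  magnitude 1.4, vanishing asymptotically. This is a property of the
  estimand, not of the optimizer — the ML estimate matches a closed-form
  method-of-moments oracle replicate by replicate.
- The equality-constrained pooled estimates are scale-dependent (tying two
  paths is only meaningful when the two predictors share units);
  rescaling equivariance holds for the unconstrained models.
- Item response theory, measurement-invariance testing, robust/weighted
  estimators, bootstrapped SEs and indistinguishable-dyad methods are out
  of scope.
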