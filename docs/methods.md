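# Methods

This note documents the statistical model, the synthetic-data generators,
the numerical choices, and the known limitations of `sensmed`.

## The path model

The observed variables are one parenting-style score P (permissive,
authoritarian, or authoritative — one style per model family), observed
environmental sensitivity ES, rumination M, and depressive symptoms Y9 and
Y12 at two later waves.  All variables are z-scored with the sample mean and
SD (n−1 denominator) before fitting, so every coefficient is a standardised
B.  The interaction regressor is the product of the two z-scores — the
dominant convention in moderation analysis — and is then mean-centred, which
only absorbs the intercept: after z-scoring, every response and every other
regressor has exactly zero mean, so no intercepts appear in any equation and
slopes are unchanged.

The full recursive system is

    M   = a·P + w·ES + k·(P×ES) + e1,   e1 ~ N(0, σ1²)
    Y9  = c1·P + b1·M            + e2,   e2 ~ N(0, σ2²)
    Y12 = c2·P + b2·M            + e3,   e3 ~ N(0, σ3²)

with mutually independent residuals.  Exogenous variables (P, ES, P×ES) are
conditioned on, not modelled.  Because the system is recursive with
independent residuals, the likelihood factorises over equations and maximum
likelihood equals per-equation OLS — which the package exposes (`fit_ml`) as
a frequentist oracle for testing the Bayesian machinery.

Four nested variants: *null* (variances only), *mediation* (a, b1, b2, c1,
c2), *additive* (adds w), *interaction* (adds k).  Sex is generated for
realism but never enters a fitted model, since the study design reports no
sex paths.

### Null-model variable scope

The published selection table implies the null model evaluated the density
of roughly six variables while the substantive models evaluate three
conditional densities — an inconsistency the source leaves unexplained.  Both
conventions are implemented: `endogenous_only` (M, Y9, Y12; scope-compatible
with models 1–3) and `all_variables` (adds P, ES, P×ES, reproducing the
published deviance magnitude of ~3300+ for the null).  `log_bayes_factor`
refuses scope-mismatched comparisons unless `allow_scope_mismatch=True` is
passed; the pipeline passes it when configured for the `all_variables`
convention.  Neither convention is asserted as "the" published intent, and
the published absolute Loo IC / log-BF values are not test targets.

## Priors

Standardised-scale normal priors encode the study's expectations, with signs
flipped for authoritative (protective) parenting:

| parameter | permissive | authoritarian | authoritative |
|-----------|------------|---------------|---------------|
| a (P→M)   | N(0.1, 0.1)  | N(0.1, 0.1)  | N(−0.1, 0.1) |
| c1 (P→Y9) | N(0.1, 0.1)  | N(0.1, 0.1)  | N(−0.1, 0.1) |
| c2 (P→Y12)| N(0.05, 0.1) | N(0.05, 0.1) | N(−0.05, 0.1)|
| b1 (M→Y9) | N(0.50, 0.10) | same | same |
| b2 (M→Y12)| N(0.35, 0.10) | same | same |
| w (ES→M)  | N(0, 0.2) sceptical | same | same |
| k (P×ES→M)| N(0.3, 0.1) | N(0, 1) | N(0, 1) |

Residual scales get gamma(shape 1, rate 0.5).  The source names the
distribution but not the parameterised quantity; the package defaults to
placing it on the residual **SD** (the modern default of the reference
Bayesian-SEM software) with `variance` and `precision` parameterisations
available behind a switch.  At n = 196 the choice moves the six path
posterior means by < 0.01 (asserted in the test suite), so it is immaterial
for the study-scale conclusions.

## Sampler

The posterior has at most ten parameters and is nearly Gaussian, so
gradient-based sampling is unnecessary.  `fit_mcmc` uses componentwise
adaptive random-walk Metropolis within Gibbs over per-equation Gram-matrix
sufficient statistics (XᵀX, Xᵀy, yᵀy), making each update O(p²) in the
equation's predictor count and independent of n.  Details:

* Defaults: 4 chains × 8000 iterations, first half discarded as warm-up
  (≥ 4000 retained per chain).  The warm-up fraction is a package choice (the
  source does not state one).
* Proposal scales start at 2.5·min(prior SD, n^−1/2) for paths and 0.1·σ̂ for
  scales, and are multiplicatively adapted every 50 warm-up iterations
  toward a 20–40% acceptance window; adaptation freezes at the end of
  warm-up, preserving detailed balance for the retained draws.
* Initialisation: ML estimates jittered uniformly by up to ±2 prior SDs
  (overdispersion so the PSRF is meaningful).
* Convergence: split-chain PSRF with threshold 1.05 (the source names the
  statistic but no cutoff).  A failing fit is rerun with doubled iterations
  up to twice before a `ConvergenceError` carrying the report is raised.
  Note the classic estimator sits at √((n−1)/n) ≈ 0.9975 when chains are
  identical, slightly below 1.
* Residual SDs are updated on their natural scale; proposals below zero are
  rejected through the prior support.  Residual variances can be pinned
  (`fix_resid`) to expose conjugate sub-models for closed-form testing.

Sampler correctness is established by oracle equivalence rather than by
reference to any specific sampler: prior washout (scales ×10⁴) reproduces
OLS; a conjugate one-predictor sub-model with fixed variance reproduces the
analytic posterior mean and SD; tiny prior scales pin posteriors to the
prior location; seeds are bit-reproducible.

## Model comparison

* **PSIS-LOO** (`loo_ic`): pointwise log-likelihood over all retained draws,
  Pareto-smoothed importance weights (smoothing delegated to
  `arviz.psislw`), reported as −2·elpd with p_loo and per-observation Pareto
  k.  More than 10% of k > 0.7 attaches a warning, not an error.
* **Evidence**: Laplace approximation at the posterior mode in the
  (paths, log σ) parameterisation, with the change-of-variables Jacobian
  folded into the prior; Hessian by central finite differences.  Because the
  posterior is near-Gaussian, the optional bridge-sampling refinement
  (optimal bridge, normal proposal matched to half the draws) agrees with
  Laplace to ~0.02 on study-scale fits, and both agree with the analytic
  evidence of a conjugate sub-model to < 0.1.
* **Weights**: pseudo-BMA with Bayesian-bootstrap regularisation (default),
  raw pseudo-BMA, or stacking of predictive distributions.  The published
  table's pairwise "weight against the previous model" is reproduced as the
  two-model weight.

## Effect interpretation

ROPEs: (−0.1, 0.1) for direct standardised effects, (−0.01, 0.01) for
indirect, (−0.02, 0.02) for conditional indirect effects.  The overlap index
is computed by interval arithmetic on the HPDI endpoints; a sample-proportion
variant (`sample_rope_index`) is provided because published values are
occasionally one rounding step from the endpoint computation.  A zero-width
HPDI yields 0 if the point is inside the ROPE, 1 otherwise.

Derived effects are always computed draw-wise (mean of products, never
product of means).  The conditional indirect effect defaults to (a + k)·b —
the indirect effect for a child one standardised unit above mean
sensitivity — with a general `at_sensitivity=e` option giving (a + k·e)·b.
Bayesian R² per equation is var(Xβ)/(var(Xβ) + σ²) per draw.  Extreme-group
slopes use the empirical mean standardised sensitivity of the bottom/top 30%
(≈ ∓1.159 under normality); the tail cutoff value is available as an
alternative convention.

## Synthetic data

`study_moments()` carries the published descriptive table: eight variables
(ES, sex, three parenting styles, rumination, two depression waves), their
means and SDs, and the full correlation matrix, N = 196.  Sex is a 0/1
indicator with printed mean 0.43 and no printed SD; it is carried as the
Bernoulli value √(p(1−p)) ≈ 0.495 and can be binarised by latent-normal
thresholding, which approximately reproduces the printed point-biserial
correlations.  The printed matrix is positive definite (smallest eigenvalue
0.45), so the eigenvalue-clipping repair for rounding-broken matrices is
implemented and tested but never fires on the study values.

`generate_mvn(..., exact=True)` whitens a normal draw with the Cholesky
factor of its own sample covariance and recolours it with the target
correlation factor, so the *sample* moments equal the targets to machine
precision.  Consequences worth understanding:

* For models whose regressors are all pinned by the moment table (the
  mediation and additive variants), the z-scored Gram matrices — hence the
  entire likelihood — are identical across seeds, and the published
  posterior summaries become sharp targets (reproduced to ±0.03).
* The interaction model additionally depends on the product regressor's
  sample covariances, which the moment table does not pin down; its k
  posterior therefore varies across synthetic samples and is checked by
  parameter-recovery and model-selection properties, not by value.

`generate_structural` simulates the recursive system forward from known
coefficients with independent standard-normal P and ES (optionally
skew-normal ES), validated at n = 10⁵ against a path-tracing covariance
oracle.  `residuals_for_unit_variance` solves for residual variances that
put every endogenous variable on the unit-variance scale, so structural
scenarios live on the same standardised scale as the fitted models.
Recovery and selection experiments default to the permissive-model posterior
values (a = 0.08, w = 0.11, k = 0.23, b1 = 0.40, b2 = 0.22, c1 = 0.06,
c2 = 0) at N = 196, the study's own effect sizes and sample size.

`generate_items` produces one-factor continuous item data with equal
loadings; the population Cronbach's alpha is the closed-form
k·λ²/(1+(k−1)λ²), inverted by `loading_for_alpha`.  Reliability intervals
use the Feldt F-distribution method by default (the source does not name
its method), with a respondent bootstrap as an alternative.

What the generators do **not** emulate: item-level ordinality of the real
questionnaires (the seven study variables are generated as continuous),
missingness and attrition (the study's imputation analysis is out of scope),
and the true shape of the observed sensitivity distribution.  Passing tests
therefore demonstrate fidelity of the *machinery* under the published moment
structure, not robustness to those real-data features.

## Problem sizes and test design

The acceptance-grade fits use the full study defaults (4 chains × 8000
iterations at N = 196; about a second each on the Gram-matrix sampler).
Replicated experiments use deliberately reduced settings chosen as the
smallest sizes at which the checked property is stable: 50 recovery
replicates and 40 selection replicates at N = 196 with 2 chains × 2400 and
2 chains × 1600 iterations respectively.  All randomness is seeded;
hypothesis-style property checks use fixed generators.

## Known limitations

* The figure-level extreme-group slopes printed in the source (−0.03 low /
  0.16 high) are not derivable from the printed a = 0.08, k = 0.23 under any
  symmetric standardised-ES convention (both implemented conventions give
  ≈ −0.19/0.35); the original values must reflect the unobserved empirical
  ES distribution or a different slope definition.  They are therefore
  covered by direction checks only.
* The published age-12 conditional indirect summary (mean outside its own
  interval) is internally inconsistent, treated as a typographical error,
  and excluded from numeric checks.
* The Laplace evidence assumes a unimodal, near-Gaussian posterior — true
  for these models, not for path models generally; use the bridge option
  when in doubt.
* The sampler is not meant for high-dimensional SEMs; it exploits the
  factorised recursive-likelihood structure of exactly this model family.
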