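# Methods

## The problem

Longitudinal and otherwise clustered data with a non-normal response are
usually modeled with generalized linear mixed models (GLMMs) or generalized
estimating equations (GEE). Both approaches demand a commitment the analyst
rarely can defend: the GLMM requires the random-effects structure to be
specified correctly (random intercept? random slope? correlated?), and GEE
requires a working correlation, with fragile small-sample behavior of the
sandwich variance. Mistakes in either commitment translate directly into
invalid tests on the regression coefficients.

`flip2sss` takes a different route. It combines the *two-stage
summary-statistics* idea (reduce every cluster to the coefficients of its own
within-cluster GLM, then model those coefficients across clusters) with a
*standardized sign-flipping score test* in the second stage. The sign-flip
test's robustness to variance misspecification is what makes the combination
work: the between-cluster variability induced by random effects, unequal
cluster sizes and within-cluster dispersion all end up as heteroscedasticity
of the stage-2 errors, which the flip test tolerates without ever modeling it.

## The test statistic

For a GLM with design `X`, tested column `d`, nuisance columns `X_{-d}` and
IRLS weight matrix `W` evaluated at the null-restricted fit, the *effective
score* for `beta_d` is

    S = sum_i nu_i,
    nu_i = (X_d - X_{-d} (X_{-d}' W X_{-d})^{-1} X_{-d}' W X_d)_i (y_i - mu_i),

i.e. the tested column is orthogonalized against the nuisance block in the
`W` metric (through `W^{1/2}`-residualization; the weight factors cancel in
the per-unit contribution, which keeps zero-weight observations well
defined). At the restricted MLE the nuisance score vanishes, so `S` is also
the gradient of the profile log-likelihood in `beta_d` — the identity the
test suite checks numerically for all three families.

A sign-flip transformation multiplies each contribution by ±1. For each of
`B` flips `F` (identity first) the flipped score `S_F = sum_i F_i nu_i` is
studentized with a flip-specific standard-deviation estimate

    sigma_F = sqrt( sum_i nu_i^2 - S_F^2 / n ),

and the two-sided p-value is the fraction of flips with `|S_F/sigma_F|` at
least the observed value, ties counted as extreme and the identity flip
included — which guarantees `p >= 1/B` and finite-sample validity whenever
the contributions are independent and symmetrically distributed around zero.
For `n` small enough that `2^n <= B` the ensemble enumerates all `2^n` sign
vectors and the test is free of Monte-Carlo error (and seed-invariant).

For a block of `k` coefficients the `k` standardized flipped scores are
combined by a Mahalanobis quadratic form `T_F = s_F' Sigma^- s_F`, where
`Sigma` is the *uncentered* second-moment matrix of the flip ensemble and
`Sigma^-` a pseudo-inverse. Using the ensemble moment instead of a
model-based information matrix is deliberate: the test does not need the
Fisher information to be estimated correctly, and the uncentered form makes
the `k = 1` case collapse exactly onto the two-sided scalar test.

## The two-stage procedure

**Stage 1.** For each cluster `j` fit the within-cluster GLM (intercept plus
the covariates that vary inside clusters) by ML or by Firth bias-reduced
logistic regression, giving the N×h summary matrix of estimates. Aliased
columns (detected by sequential Gram–Schmidt with relative tolerance 1e-10;
earlier columns win, so the intercept is never dropped for a constant
covariate) are recorded as inestimable cells, not errors. Clusters with a
single observation contribute only to the intercept column. For binomial ML
fits, iteration stops and a separation flag is raised once `|eta| > 15` —
complete separation makes the ML estimate infinite, and the capped value is
kept (with its diagnostic flag) rather than discarded.

**Stage 2.** Column `k` of the summary matrix is regressed on the
between-cluster covariates that the *mask* allows for that column. The mask
comes from the model formula: a between main effect models the
within-intercept column; a `between:within` interaction additionally lets
that between term model the corresponding within-slope column. Every
stage-2 coefficient gets a standardized sign-flip score test with the other
unmasked terms of its column as gaussian nuisance; each between covariate
additionally gets an ANOVA-like combined test pooling its dummy columns
across all within-columns via the Mahalanobis form. One flip ensemble,
indexed by sorted cluster id, is shared by every test — this preserves the
joint null distribution across the h second-stage models and makes all
p-values invariant to cluster reordering. A cluster inestimable for a column
contributes exactly zero to that column's flipped sums but keeps its flip
assignment for the other columns.

The reported `estimate` column is the masked-model OLS coefficient; it is
descriptive only — inference comes exclusively from the flip distribution.

## Why Firth in stage 1

The method's one substantive assumption is (asymptotic) unbiasedness of the
stage-1 estimates. With few observations per cluster and a binary response,
complete separation is routine and the ML estimates are infinite or, as
implemented, capped at the divergence threshold — enormously variable either
way. The Firth correction (Jeffreys-prior penalization, solved here by
modified-score IRLS: the working residual gains the term `h_i (1/2 - mu_i)`
with `h` the hat diagonal) keeps every estimate finite and reduces the
leading-order bias, which restores power at small cluster sizes. The default
first-stage estimator is therefore `firth` for binomial models and `ml`
otherwise. The Firth IRLS uses oscillation damping (the step is halved when
its direction reverses) because plain Fisher scoring two-cycles on
near-saturated fits; fits are cross-checked in the tests against direct
numerical maximization of the penalized log-likelihood.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `B` | 5000 (1000 in simulations) | flip ensemble size; exhaustive when `2^N <= B`; p-values have resolution `1/B` |
| `seed` | required | controls the single flip ensemble shared by all tests of a fit |
| `stage1_estimator` | `firth` (binomial), `ml` otherwise | stage-1 fitting; Firth needs `max_iter` 200 vs 100 |
| `tol` | 1e-8 | IRLS convergence on max absolute coefficient change |
| separation threshold | 15 on `|eta|` | practical divergence proxy for monotone likelihood |
| alias tolerance | 1e-10 relative | sequential rank detection in any design matrix |

## The simulation design

`sims` generates two-level binary data from a random-intercept,
random-slope logistic model: per cluster `b0 ~ N(0, sd0^2)`,
`b1 ~ N(0, sd1^2)`; per observation `X ~ N(0,1)`, `Z = X + N(0,1)`
(correlation `1/sqrt(2)`), and

    logit P(Y=1) = beta*X + eta*Z + b0_j + b1_j*X,

with defaults `eta = 1`, `sd0 = sd1 = 1`, `beta = 0` for level studies and
`beta in {0.25, 0.5, 1}` for power. Balanced designs use a constant `n_j`;
the unbalanced rule draws `n_j` uniformly on `{2, ..., 2*n_bar}`. Testing
the within-cluster effect `beta` through the two-stage method means testing
the stage-2 *intercept* of the X-slope column — the mean of the per-cluster
X-slopes — with the shared-flip standardized score test. Comparators: a
naive logistic GLM with Wald test (ignores clustering entirely) and GEE with
independence working correlation, both via statsmodels. GLMM comparators are
out of scope and reported as not run.

Problem sizes in the shipped tests and the acceptance script (grids over
`N ∈ {10, 25, 50}`, `n_j ∈ {4, 8}`, 500–1000 replicates, `B = 1000`) are the
package's desk-scale study; report-quality runs should raise `n_reps` to
5000 via the scenario config.

## What the generator does and does not emulate

It reproduces the structural difficulties the method targets: cluster-level
random effects of both kinds, a correlated within-cluster nuisance, small
and unequal cluster sizes, frequent complete separation in stage 1. It does
not emulate non-random missingness, covariates with measurement error,
crossed or >2-level hierarchies, or time-structured within-cluster
correlation beyond what the random effects induce — passing simulations say
nothing about those regimes.

## Validity: exact, and where only approximate

The flip test is *exact* (finite-sample, any `N`) when the per-unit
contributions are independent and symmetric — the test suite verifies this
directly with exhaustive enumeration. Two things erode exactness in real
use, both documented deliberately:

1. **Nuisance-fit coupling.** Once contributions are residuals from a fitted
   nuisance model they are no longer independent; validity is asymptotic and
   the null level carries an `O(1/N)` inflation. Under a harsh
   heteroscedastic gaussian design (`sd ∝ |x|`, n = 100) the measured level
   is ≈ 0.055 at nominal 0.05, against ≈ 0.23 for the naive t-test.
2. **Stage-1 bias.** The stage-2 test is a test of *zero mean* of the
   summary estimates. Any finite-sample bias of the stage-1 estimator is
   inherited as level inflation growing with `sqrt(N)`. Under the default
   simulation settings (strong nuisance effect, unit random-effect
   variances, 3 within-parameters at `n_j ∈ {4, 8}`) the Firth slope
   estimates retain a small negative bias, and the measured level at
   `N = 50` sits near 0.06–0.07. The flip machinery itself is exact on the
   same estimates once symmetrized, which isolates the cause. Milder
   generative settings or larger `n_j` remove the effect.

The standardization denominator used here is the ensemble form
`sigma_F = sqrt(sum nu_i^2 - S_F^2/n)`; it does not re-residualize the
flipped contributions against the nuisance design, which is the price behind
point 1. Every run log records the standardization formula in use.

## Other design choices

- **p-value convention**: identity flip counted in numerator and
  denominator; ties count as extreme. Conservative and guarantees validity.
- **Combined-test granularity**: one ANOVA-like test per between covariate,
  pooling its dummy columns across all within-columns where it is unmasked;
  per-column scalar tests remain available in the coefficient table.
- **Stage-2 intercept**: always included as nuisance and also tested (it is
  the quantity of interest when a within-effect's mean is the target, as in
  the simulations).
- **Factor coding**: treatment contrasts, alphabetically first level as
  reference.
- **Degenerate inputs**: all-zero contributions give statistic 0 and p = 1
  with a warning; singular nuisance Gram matrices fall back to a
  pseudo-inverse; a tested column aliased with the nuisance design is a hard
  error.
- **Dispersion**: fixed at 1 for binomial/poisson; for gaussian models it
  cancels from the standardized statistic and is only reported.

## Known limitations

- Two-level hierarchies only; no crossed random effects, no multivariate
  (multi-response) stage 2.
- Canonical links only (identity/logit/log); no quasi-families, offsets are
  supported but prior weights are not.
- Inference quality is bounded by stage-1 estimate quality: with very small
  `n_j` and many within-covariates, expect conservative ML behavior or the
  residual-bias inflation described above.
- The Mahalanobis combination uses the flip-ensemble moment; with very small
  `B` and many combined components its pseudo-inverse becomes noisy.
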