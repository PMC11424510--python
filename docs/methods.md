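# Methods

## Problem and estimands

For a response `Y` and feature blocks `X` and `Z`, the question "does `X`
add predictive power for `Y` beyond `Z`?" is formalized as a test of the
conditional independence null `Y ⟂ X | Z`, operationalized through
regression residuals so that any sufficiently predictive supervised
learner can be plugged in.

Two population functionals are targeted. With population residuals
`ε = Y − E[Y|Z]` and (for one-dimensional `X`) `ξ = X − E[X|Z]`:

- **GCM.** Under the null, `E[ε ξ] = 0`. The generalised covariance
  measure test estimates both residual vectors and compares the
  standardized squared mean of the products `ε̂ᵢ ξ̂ᵢ`,

  `T = (n^{-1/2} Σ ε̂ᵢξ̂ᵢ)² / (n^{-1} Σ ε̂ᵢ²ξ̂ᵢ² − (n^{-1} Σ ε̂ᵢξ̂ᵢ)²)`,

  to a χ²₁ distribution. In the partially linear model
  `E[Y|X,Z] = θX + h(Z)` the target is proportional to `θ`, so the GCM is
  the natural "all-purpose" test for (approximately) linear signal. It can
  be blind: `E[ε ξ]` may vanish under dependence (e.g. `Y = X²` with
  `X, Z` independent standard normal, where `E[(X²−1)X] = 0`).

- **PCM.** `τ = E[(E[Y|Z] − E[Y|X,Z])²]` is strictly positive exactly when
  `X` helps predict `Y` in mean-squared error. The projected covariance
  measure test learns, on half the sample, a direction
  `f̂(x,z) = (ĝ(x,z) − m̂(z)) / v̂(x,z)` from regressions `ĝ ≈ E[Y|X,Z]`,
  `m̂ ≈ E[Y|Z]` and `v̂ ≈ Var(Y|X,Z)` (regression of squared ĝ-residuals
  on `(X,Z)`), and on the other half forms residuals `ε̂` (Y on Z) and
  `ζ̂` (f̂(X,Z) on Z). The standardized mean product is compared one-sided
  to a standard normal. `X` never appears as a regression response, so the
  PCM's cost does not grow with the dimension of `X` and `X` may be any
  block a plugged-in learner accepts.

## Algorithmic choices

**Multivariate GCM aggregation.** For `X ∈ R^d` the per-coordinate
products `Rᵢⱼ = ε̂ᵢ ξ̂ᵢⱼ` are aggregated as a quadratic form
`T = n R̄ᵀ Σ̂⁻¹ R̄` against χ²_d (Σ̂ the empirical product covariance,
maximum-likelihood normalization so the d = 1 case reduces exactly to the
univariate statistic), or as a max-type statistic
`max_j |√n R̄ⱼ|/σ̂ⱼ` calibrated by a Gaussian multiplier bootstrap
(B = 499, seeded). These are the two standard aggregations for
residual-product tests. Default: quadratic for `d ≤ min(25, n/10)`, max
otherwise. A singular Σ̂ falls back to the Moore–Penrose pseudo-inverse
with the rank as effective degrees of freedom, with a logged warning;
`d ≥ n` is refused with a pointer to the PCM.

**Residualization.** GCM regressions are in-sample by default (the
procedure requires no splitting); k-fold cross-fitted residuals are
available (`mode="cross_fit_kfold"`, seed-deterministic folds) for
flexible learners where overfitting bias is a concern. Binary `X` columns
(e.g. mutation indicators) are residualized on the probability scale via
a classification learner: residual = value − predicted probability.

**PCM splitting and aggregation.** `n` rows are split into halves D1/D2
(odd `n` puts the extra row in D1); nuisances are fitted on D2 and the
statistic evaluated on D1, never on training rows. K random splits
(default 5; 5–10 is the practical range) are aggregated by averaging the
per-split statistics and taking the one-sided normal tail at the mean.
This is conservative — the average of dependent standard normals has
variance at most one — trading a little power for stability; an exactly
calibrated multi-split combination exists in the literature but is
deliberately not implemented. `swap_halves=True` additionally exchanges
the roles of D1/D2 within each split (doubling the effective K).

**Variance floor.** The estimated conditional variance is clipped below
at `max(1e-6, 0.01 × median(v̂))` over the evaluation rows, with a logged
warning and a per-split `floor_hits` diagnostic. This prevents division
blow-ups without materially changing the direction of f̂. Beyond the
floor, no finite-sample corrections to f̂ are applied; this is a
documented divergence from the fullest published form of the procedure.

**Variance regression default.** `spec_var` defaults to `mean_only`
(constant variance: the mean of squared ĝ-residuals). In simulation
studies where all regressions are forests, `spec_var` is also a forest.
This matters in practice: on the product DGP below, a forest v̂ learns
where ĝ errs (the heavy `1 + z³` tails), and the inverse-variance
weighting tames exactly the tail residual products that otherwise
dominate the statistic's denominator — measured PCM rejection at n = 600,
K = 5 rises from ~0.3 with a constant v̂ to ~1.0 with a forest v̂, while
null sizes remain conservative.

**Degeneracy.** A residual-product vector with zero variance makes either
statistic undefined; the package raises a `DegenerateStatisticError`
rather than reporting p = 1 (a constant f̂, e.g. from a constant
response, is the typical cause). The harness counts and excludes
degenerate replicates explicitly; for all shipped DGP/test combinations
at n ≥ 200 the count is zero.

## Learners

The regression contract is algorithm-agnostic; bundled learners are
scikit-learn estimators: `mean_only`, `linear` (OLS / logistic),
`lasso_cv` (10-fold CV-optimal penalty; L1 logistic for binary targets)
and `random_forest` (500 trees, `mtry ≈ √p`, minimum node size 5 for
regression — mirroring the R reference implementations these tests are
usually run with; forests need essentially no tuning). A constant target
under `lasso_cv` falls back to `mean_only` with a warning. User learners
register via `register_learner` and need only fit/predict
(`predict_proba` for binary targets).

Simulation studies in the test suite and acceptance script run forests
with 100 trees: rejection-rate estimates over hundreds of replicates are
insensitive to the difference between 100 and 500 trees on the
low-dimensional DGPs used there, and the smaller forests keep the studies
at desk scale. Single-dataset analyses use the 500-tree default.

## Synthetic DGPs

All generators are seed-deterministic; those with closed-form conditional
means expose exact oracle residuals so calibration can be checked
independently of learner quality.

| DGP | structure | role | defaults |
|---|---|---|---|
| `fig2_product` | `Y = (1+sin(3X²))(1+Z³) + σN`, X,Z iid N(0,1) | GCM-blind, PCM-visible alternative | σ = 0.5 |
| `quadratic_blind` | `Y = X² (+σN)`, X ⟂ Z | population-level GCM blindness | σ = 0 |
| `partially_linear` | `Y = θX + cos(2Z̄) + σN`, `X = 0.5Z̄ + N(0,1)` | GCM power proportional to θ; exact null at θ = 0 | σ = 1 |
| `pure_null` | `Y = Z̄ + σN`, X linearly dependent on Z | null where linear learners are correctly specified | σ = 1 |
| `block_multimodal` | 3 latent-factor-correlated blocks, binary event driven by block 3 | modality-selection shape | — |
| `binary_panel` | sparse 0/1 columns, response driven by 3 columns | mutation-panel shape | σ = 1 |

(`Z̄` denotes the normalized sum of the `d_z` conditioning columns.)

The product DGP's distributions, noise and sample size are not pinned
down by its original graphical presentation; the completion above
(standard normal inputs, additive noise with σ = 0.5) was fixed once as a
realistic smooth-signal regime and all power statements refer to it. The
`1 + z³` factor makes `E[Y|Z]` extremely heavy-tailed under normal `Z`,
which is the binding difficulty for any plugged-in learner on this DGP.

These generators emulate the dependence *structure* of real multimodal
data (dimensions, block layout, binary coding), not real marginal
distributions, batch effects, missingness or imputation artifacts.
Passing level/power checks on them demonstrates that the test statistics
and their calibration behave as the theory predicts when the learners are
adequate; it does not certify type-I control on data where the plugged-in
learners cannot estimate the conditional means well.

## Study conditions used by the shipped simulations

- GCM level: `pure_null`, linear learners (correctly specified), n = 300,
  500 replicates; exact binomial check at α = 0.05 plus a KS uniformity
  check of the p-values.
- PCM conservativeness: `pure_null` and `partially_linear(θ=0)`,
  all-forest learners, n = 400, K = 5, 100 replicates each (200 pooled).
- Product DGP contrast: n = 600, 100 replicates, all-forest learners;
  PCM rejection ≥ 0.8 and GCM ≤ 0.15 at α = 0.05.
- Power monotonicity: θ ∈ {0, 0.25, 0.5}, n = 500, 200 replicates,
  linear learners (valid because `E[X|Z]` is exactly linear in this DGP
  regardless of `h`).
- Analytic zero: 10⁶ Monte-Carlo draws of the oracle products for the
  quadratic example; the estimate must sit within 3 standard errors of 0.

Replicate counts and sample sizes were chosen to make the binomial and
Monte-Carlo error bars decisively smaller than the margins being checked.

## Known limitations

- The multi-split PCM p-value is conservative by construction; exact
  multi-split calibration is out of scope.
- No survival/censored-response learners are bundled; binary responses
  are supported through probability-scale residuals.
- Holm is the only multiplicity correction provided.
- Timing comparisons are hardware-dependent; only the regression-count
  crossover (GCM: d + 1 fits; PCM: 5 per split independent of d) is
  asserted.
- Missing values are rejected, not imputed; imputation belongs upstream
  and its validity is the caller's responsibility.
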