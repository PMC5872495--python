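# Methods

## Linear stacking

Given component predictions `ỹ = [y_1, …, y_{N_m}]` for held-out samples,
the stack is the affine least-squares fit `y_f = ỹ·w + b` of the held-out
responses on the component outputs. Because the design with intercept nests
each single component (weight one on it, zero elsewhere), the stacked MSE
on the fitting set is never larger than any component's — this is exact and
asserted exactly in the tests. On a disjoint test set dominance is expected
but not guaranteed. Rank-deficient designs (duplicated or collinear
components, which arise naturally when two models are trained on the same
features) are resolved by the minimum-norm least-squares solution with a
warning rather than an error.

## Hierarchical-Bayes account of debiasing

Tree predictions are modeled as conditionally independent
`Z_j ~ N(βμ, σ²)`, j = 1…T, with multiplicative bias β (β > 1
overprediction, 0 < β < 1 underprediction; additive bias α is carried as a
field but fixed to 0, the case in which the closed forms below hold — in
the regression formulation of stacking the fitted intercept plays the role
of an estimate of the average additive bias). A second model contributes
the prior `μ ~ N(μ_m, τ²)`. The conditional posterior of μ is Normal(λ, ν²)
with

    ν² = (1/τ² + Tβ²/σ²)⁻¹
    λ  = [Tβτ²/(σ² + Tβ²τ²)] Z̄ + [σ²/(σ² + Tβ²τ²)] μ_m .

`posterior()` implements these forms; `posterior_quadrature()` is an
independent numeric check that integrates the unnormalized posterior
density on a dense grid (default 40 001 points) spanning both plausible
centers `Z̄/β` and `μ_m` padded by 12 standard deviations of the wider
component; agreement is verified to 1e−6 (observed agreement is at machine
precision). `regime_report()` classifies the qualitative behaviour using
two package-level thresholds: the variance condition σ² ≪ τ² is read as
τ²/σ² ≥ 100, and Cβ ≫ 1 (C = Tτ²/σ²) as Cβ ≥ 10. Two labels beyond the
canonical four cover the boundary cases β = 1 ("unbiased-shrinkage") and
1 < Cβ < 10 ("underprediction-intermediate").

In practice none of β, σ², τ² need to be estimated: regressing held-out
responses on the component predictions (ordinary linear stacking) estimates
the coefficients of Z̄ and μ_m directly.

## Horizontal vs vertical stacking

With the number of terminal nodes k held constant, an RF's prediction
variance is of order k/n. The horizontal design trains its first component
on n₁+n₂ samples (variance ~ k/(n₁+n₂)) and its second on n₂ samples
(~ k/n₂), so the variance condition σ² < τ² holds by construction and
strengthens as n₁ grows. The vertical design cannot enforce it when
n₂ < n₁. The learning-curve experiment measures the consequence: lower test
MSE and lower bias angle for the horizontal stack at every training size.

## Bias diagnostics and correction baselines

* **Bias angle.** Residuals use the convention r = observed − predicted
  throughout; θ is arctan (degrees) of the OLS slope of r on the observed
  values, computed on test-set residuals. θ = 0 for an unbiased predictor;
  predicting the observed mean everywhere gives slope exactly 1, θ = 45°.
  Bootstrap CIs resample (observed, predicted) pairs jointly, 1000
  resamples by default, percentile 2.5/97.5 bounds; degenerate resamples
  with constant observed values are redrawn.
* **Eigen diagnostic.** The covariance of the column-centered component
  residual matrix is eigen-decomposed; eigenvalues are clipped at zero
  (guarding tiny negative round-off), normalized to sum to one and sorted
  descending. The variance-condition flag fires when the dominant fraction
  exceeds 0.9. An all-zero residual matrix returns a flagged degenerate
  report instead of dividing by zero.
* **BC1.** A second forest maps validation covariates to validation
  residuals; corrected prediction = base + predicted residual. The
  validation set must be disjoint from the base model's training data.
* **RRot.** The residual-vs-predicted OLS line on validation (slope s,
  centroid (p̄, r̄)) is rotated to horizontal about the centroid; the
  correction added to a prediction ŷ is the vertical gap s·(ŷ − p̄) between
  the original and rotated lines. Algebraically the post-correction
  residual-vs-predicted slope on validation is exactly zero, which also
  makes the map idempotent. Only this end-state contract is implemented;
  constant validation predictions yield the identity map with a warning.
  The degenerate slope s = −1 (perfectly anti-correlated trend) collapses
  the corrected predictions to a constant and is not handled specially.

## Base predictors

All predictors output averages of training responses and are therefore
bounded by the training response range.

* **Forest.** scikit-learn's `RandomForestRegressor` behind the package's
  configuration surface: bootstrap per tree, `m = ceil(feature_fraction·M)`
  candidate features per split (default fraction 1/3), and a node below
  `min_node_size` samples is a leaf (default 5, configurable; clamped to
  scikit-learn's minimum of 2, which is semantically identical since a
  one-sample node cannot split). Per-tree bootstrap indices remain
  accessible so that single-tree/no-split behaviour can be recomputed from
  first principles in tests.
* **Taxicab KNN.** Distance is the L1 sum of absolute coordinate
  differences — appropriate for sparse binary target profiles, where it
  counts disagreeing targets. k = 5 by default. Ties at the k-th distance
  are broken by the lowest training index (stable sort), making predictions
  deterministic; the direct variant averages the raw responses of the k
  nearest profiles, the residual variant averages mean-centered residuals
  and adds the target drug's training-set mean back. Drug means are always
  computed on the training partition only.

## Target-potency curation

Reported K_d/EC50 values (assumed micromolar) for a drug–target pair are
filtered by order of magnitude: m = floor(log10 t) per value, values with
|m − mode(m)| > 3 removed (the filter's purpose is catching nano-/micromolar
unit misreports), survivors summarized by their median (midpoint of the two
central values for even counts). Mode ties are broken toward the smallest
magnitude, favouring the more potent measurements. The modal-magnitude
values always survive, so curation never empties the list. Binarization
calls a target inhibited (1) when the curated value is strictly below half
the drug's maximum tested dose.

## Synthetic data

* **Linear benchmark.** A 2000 × 100 standard-normal covariate matrix; a
  random half of the features get "weak" weights ~ U(0, 0.5), the rest
  "strong" weights ~ U(1.5, 3). The response is the linear combination plus
  an intercept of 1.4 and Gaussian noise with variance 3% of the sample
  variance of the noiseless response, then min-max rescaled to span exactly
  [−1, 1] (the simplest affine map achieving the stated range; noise and
  intercept are added before normalization). Normalization is
  per-replicate: each replicate regenerates all 2000 samples independently.
  Replicates are partitioned 100 (initial training) / 50 (stacking
  validation) / 500 (test), the rest held in reserve for the learning
  curve. The two training sample groups are formed by a 50:50 split of the
  training pool (the layout's n₁:n₂ ratio is not otherwise constrained) and
  each learning-curve step moves 20 reserve samples into *each* group, so
  consecutive total training sizes differ by 40. The feature split is
  stratified: half the weak and half the strong features per side, ensuring
  each side carries at least 25 of each kind at the default dimensions.
  All per-replicate randomness is derived from `SeedSequence(base_seed + r)`
  spawning separate sub-seeds for generation, splitting, feature
  stratification and forests, so replicates are independent and exactly
  reproducible.
* **Pharmacogenomic simulator.** Emulates the shape of a multi-source
  screen at reduced scale (defaults: 60 cell lines × 30 drugs, 80 genes, 40
  descriptors, 25 targets): AUC(c, d) = logistic(per-drug mean effect +
  cell-line effect linear in a sparse 10% subset of genes + drug effect
  linear in the binary target profile + Gaussian noise), keeping responses
  in [0, 1]; descriptors are noisy linear readouts of the drug-level
  effects; ground-truth effects are retained for recovery checks. This is
  a synthetic stand-in: it has additive cell and drug effects, no
  gene–drug interactions, no missingness, and i.i.d. noise, so passing
  tests demonstrate the machinery and its qualitative claims
  (complementary sources stack well), not performance on real screens.
  Effect scales default to drug_effect_sd = cell_effect_sd = 0.8 against
  noise_sd = 0.15 — strong but noisy signal on the logit scale, chosen so
  that no single source suffices, which is the regime stacking is for.

## Experiment scales

The learning-curve study defaults to 20 replicates and three training sizes
(100, 140, 180) with 50-tree forests; the replicate count and size grid are
parameters, and the study design scales directly to denser grids and more
replicates. The ordering results (horizontal below vertical in both MSE and
θ) are stable across seeds at 20 replicates. The integrated study splits
the cell × drug pairs 60/20/20 into training/stacking/test; NMSE is
normalized by the per-drug mean predictor evaluated on the same test pairs,
so the mean predictor scores exactly 1.

## Known limitations

* The bias model is linear (constant β); non-linear bias is out of scope.
* Inter-tree correlation at large T is not modeled; the regime
  classification treats T as contributing precision T/σ² without a
  correlation correction.
* The eigen threshold 0.9 is a rule of thumb, exposed as a parameter.
* The closed-form posterior covers α = 0 only; nonzero α raises
  `NotImplementedError` rather than silently mis-reporting.
* The pharmacogenomic simulator makes no claim of matching real GDSC/CCLE
  performance numbers; it exercises data shapes and relative comparisons
  only.
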