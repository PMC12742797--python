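# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the test suite does and does not establish.

## Problem setting

The package targets binary CHD prediction from survey-style tabular data in
which the positive class is rare (~9–10%). Naive classifiers trained on
such data achieve high accuracy by predicting the majority class and are
clinically useless; the pipeline therefore couples class rebalancing
(SMOTE), sample-size reduction (Yamane + stratified subsampling), enhanced
learners, ensembling, and subgroup analysis into one reproducible protocol.

## Synthetic cohort generator

`chdrisk.simulate` draws 21 predictors mirroring familiar surveillance
variables — 14 binary indicators (hypertension, smoking, physical activity,
…), 4 ordinal scales (13 age bands, education 1–6, income 1–8, general
health 1–5), and 3 continuous measures (BMI, mental- and physical-health
days, the day counts zero-inflated). The outcome follows a latent logistic
model on standardized features: default effect sizes encode the usual
epidemiology (age, hypertension, poor general health raise risk; activity
and income protect) and sum to 6.5 in absolute log-odds, giving a
true-model AUC of ~0.87 — learnable but noisy, like real survey data. The
intercept is solved by bisection on the simulated latent scores so the
target prevalence (default 9.42%) is met exactly in expectation; realized
prevalence is within ±1% at n ≥ 5,000. Latent noise is standard normal
(`noise_sd = 1`).

`generate_clustered` plants k mixture components: non-binary features are
shifted by cluster offsets scaled to the `separation` parameter (in units
of feature standard deviations), binary features get cluster-specific
rates, and the outcome rate varies by cluster through odds multipliers on
the base prevalence. This supports the two recovery experiments the
subgroup analysis is tested on: adjusted-Rand label recovery at high
separation, and odds-ratio recovery (a planted OR of 4 is recovered within
±30% at n = 10,000).

What the generator does **not** emulate: real-variable marginals and
cross-correlations of any particular survey, measurement error, missingness
mechanisms beyond MCAR (tests inject MCAR missingness themselves), or
survey weighting. Passing tests therefore demonstrate algorithmic
correctness and statistical behaviour under a controlled data-generating
process, not real-data performance.

## Preprocessing

- **KNN imputation**: each missing cell is filled from the k (default 5)
  nearest fully observed rows, by Euclidean distance on co-observed
  features; continuous cells take the neighbour mean, binary/ordinal cells
  the neighbour mode with ties broken toward the smaller category.
- **Outlier flags**: per-feature IQR fences (type-7 linear-interpolation
  quantiles, multiplier 1.5) and multivariate squared Mahalanobis distance
  on continuous features against the chi-square upper-α quantile (default
  α = 0.01). A singular covariance is ridged with `1e-6·trace(Σ)/d` on the
  diagonal. Flags are reported, never silently applied — the removal rule
  is the analyst's choice (`drop_outliers` / `--drop-outliers`).
- **Variance filter** removes features with sample variance ≤ threshold;
  **scaling** is z-score (error on constant continuous features) or min-max,
  binary features passed through.

## Resampling

SMOTE interpolates `x_new = x_i + λ(x_nn − x_i)` with λ ~ U[0,1] per
synthetic sample, between a uniformly drawn minority row and one of its k
(default 5) minority-class nearest neighbours found on per-feature
standardized coordinates. The minority:majority ratio after balancing
equals `target_ratio` exactly under integer rounding toward the majority
count. Binary coordinates are thresholded at 0.5 so binary kinds stay
binary; ordinal coordinates are left on the segment, preserving the
convex-combination invariant for every non-binary coordinate.

The Yamane rule `n = N/(1 + N e²)` is computed exactly and rounded to the
nearest integer. At N = 459,574 and e = 0.01 it evaluates to 9,787.04;
write-ups of this rule sometimes quote ~9,789 for the same inputs — the
implementation keeps the exact arithmetic (9,787) rather than matching a
rounded citation.

Splits and folds are outcome-stratified with largest-remainder allocation
and are **permutation-equivariant**: rows are ordered by a seeded content
hash (BLAKE2b of the row bytes plus the seed) rather than positional RNG
draws, so relabeling rows and then splitting yields the relabeled splits.
Two orderings are supported for rebalancing: balance-then-subsample-then-
split (the benchmark default, mirroring the protocol above) and the
leakage-safe alternative of splitting first and applying SMOTE to the
training part only (`balance_first = False`); the choice is exposed because
balancing before the split lets synthetic points derived from test-side
originals influence training.

## Enhanced learners

- **ANRDT**: structure is learned as a hard greedy Gini tree (default
  depth 6, min leaf 5), then each gate is softened with steepness
  `β = β₀ / s_j` where `s_j` is the split feature's training standard
  deviation (β₀ default 4) — so the gate's transition width is a fixed
  fraction of the feature's scale. Prediction is the leaf-probability sum
  weighted by path products of gate probabilities. Pruning evaluates the
  cost-complexity (weakest-link) subtree sequence by soft-prediction
  log-loss on the validation set, ties toward the smaller tree. With
  β₀ = ∞ the gates become `x ≤ θ` indicators and predictions coincide with
  hard CART exactly (a tested equivalence).
- **HIRF**: default 200 trees (benchmark configs use fewer), each trained
  on a SMOTE-balanced bootstrap with √d feature subsampling per split.
  Tree weights: for the tree-averaging game, the Shapley contribution of a
  tree on a validation row reduces to its own signed vote toward the true
  class, so `w̃_i = mean over validation rows of max(0, p_i(true) − 0.5)`
  normalized to sum to one, with a uniform fallback when all scores vanish
  or the validation set is single-class (logged).
- **PGBM**: boosting on the log-odds scale, F₀ = prior log-odds. The Huber
  gradient is applied to the margin residual `s − tanh(F/2)` with labels
  s ∈ {−1, +1}: inside |r| ≤ δ the update is the plain residual, outside it
  is clipped at δ (default 1.0), so mislabeled or extreme points pull with
  bounded force. Depth-3 regression trees, learning rate 0.1, patience 10
  on validation log-loss, best round retained. The `ls` loss (δ → ∞) is the
  squared-loss baseline; `logistic` uses the y − σ(F) pseudo-residual.
- **ESVM**: dense-kernel dual solved by Platt-style SMO (working pair from
  the error cache, KKT tolerance 1e-3); documented solver limit n ≤ 2,000
  (O(n²) kernel memory), the benchmark harness stratified-subsamples the
  SVM training set to a configurable cap (default 400–800 rows).
  Hyperparameters (C, γ) are searched on the log₁₀ box [−2,3] × [−4,1] by
  expected improvement under a fixed-hyperparameter Gaussian process (RBF
  kernel on the unit square, length scale 0.3) over k-fold CV accuracy,
  4 seed points then EI-guided evaluations up to the budget. Probabilities
  come from a one-parameter logistic (Platt) calibration of decision scores
  on the validation set, since the dual classifier itself outputs only
  margins.

Baselines reuse the same internals as thin reference configurations: hard
CART, uniform-weight bootstrap forest, squared-loss boosting, and a fixed
(C = 1, γ = 1/d) SVM.

## Ensembles

AdaBoost uses depth-1 stumps; a round with weighted error ≥ 0.5 is re-drawn
once from a bootstrap resample, then boosting stops; a zero-error round has
α capped via ε_min = 1e-10. Gradient boosting uses depth-3 trees. Stacking
builds its meta-feature matrix from base-learner **probabilities** on the
hold-out validation rows (never test rows) and fits a logistic meta-learner
by IRLS, ridge-stabilised under separation. BMA approximates each model's
evidence by exp(validation log-likelihood) with uniform priors — the
marginal likelihood of these learners is not tractable, and the validation
likelihood instantiates the same posterior ratio with a computable
surrogate; candidate probabilities are floored at 1e-12 and weights
normalised through log-sum-exp. The "enhanced" ensemble configurations
combine {ANRDT, HIRF, PGBM, ESVM}; the "baseline" ones {CART, forest,
squared-loss boosting, fixed SVM}. Which learners entered any published
comparison row is a convention here, not a given.

## Evaluation

Score ≥ 0.5 predicts positive (stated so confusion matrices are exactly
reproducible). Metrics with zero denominators are reported as missing
(NaN) with a warning, never as 0, so fold averages are not deflated. AUC is
the tie-corrected Mann–Whitney statistic, which equals the trapezoidal area
under the empirical ROC curve (both routes are computed and tested against
each other). Average precision is the step-interpolated threshold sweep.
Cross-validated metrics are fold-averaged over stratified 5-fold CV.

## Clustering analysis

Continuous/ordinal features are z-scored, binary features pass through
(already 0/1 indicators). K-means: k-means++ seeding, Lloyd iterations,
empty clusters reseeded at the farthest point, best of the restarts by the
within-cluster sum of squares. k is chosen by mean silhouette over 2..10,
ties to the smaller k; singleton clusters contribute silhouette 0. The
association tests use the Pearson chi-square on the k×2 table (df = k−1)
and an IRLS logistic regression on k−1 cluster dummies (largest cluster
relabeled 0 as the reference), reported as coef / SE / p / OR / 95% Wald
CI. IRLS converges on relative log-likelihood change < 1e-10 (max 100
iterations); coefficients beyond |25| or non-convergence trigger a ridged
refit flagged in the output. Clustering runs on the original-scale,
pre-SMOTE cohort by default — synthetic minority points would distort
subgroup frequencies.

## Explainability

Absent features are marginalised by substituting values from a background
set (default 100 seeded training rows). The exact estimator enumerates all
2^M coalitions (guarded at M ≤ 12); the sampling estimator averages
marginal contributions over random feature permutations and spreads the
residual so local accuracy `f(x) = φ₀ + Σφᵢ` holds exactly. Attribution is
on the probability scale, matching the "pushes the prediction toward or
away from a diagnosis" reading. The surrogate is a depth-limited (default
4) hard CART fit to the explained model's predicted labels on half the
cohort, with fidelity measured on the other half.

## Numerical choices and degenerate inputs

Sigmoid exponents are clamped at ±500; log-loss probabilities at 1e-12.
Split search breaks impurity ties toward the lower feature index and
threshold. Quantiles are type-7. Seeds default to 2025 and propagate to
every stochastic stage; the end-to-end benchmark is byte-identical across
re-runs of the same config.

## Desk-scale problem sizes

Library defaults keep the published-scale settings (e.g., 200 HIRF trees).
The benchmark harness and the test suite run deliberately scaled-down
configurations — cohorts of 700–5,000 rows, 10–30 trees, SVM training
capped at a few hundred rows, GP budgets of 4–6 — chosen as the package's
desk-scale study conditions so the full protocol remains interactive.

## Known limitations

- SMOTE before splitting (the benchmark's default ordering) is vulnerable
  to optimistic bias; the train-only option exists but changes the protocol.
- The BMA evidence surrogate rewards validation fit, not marginal
  likelihood; with many candidates it can concentrate on an overfit model.
- The SMO solver is dense and quadratic in memory; it is not suitable
  beyond a few thousand rows.
- Exact Shapley is exponential in features; the sampling estimator's error
  decays as 1/√(permutations) and is tested at tolerance 0.02 on
  unit-scale outputs.
- The permutation-equivariant split hashes row content: duplicated rows
  (possible after SMOTE with thresholded binary coordinates) fall back to
  positional tie-breaking.
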