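# Methods

## Data model and preprocessing

The unit of analysis is a samples × features table with a binary outcome
(1 = positive/deceased). Preprocessing is deliberately minimal, matching
common practice for heterogeneous multi-omics tables: numeric missing values
are imputed with a constant (0 by default), categorical columns are one-hot
encoded in place (`col=level` indicator columns at the original column's
position; a missing categorical entry yields an all-zero indicator row, the
composition of zero-imputation and one-hot), and no scaling, normalization,
class reweighting or resampling is applied anywhere. A missing categorical
value is *not* given its own indicator level — that would add a feature the
two stated rules do not imply.

The encoded table's column order is frozen into `column_order` at
preprocessing time and never renumbered: it is the tie-breaking key for all
rankings, and removal of features must not perturb it, otherwise tie-broken
rankings before and after perturbation would differ for bookkeeping rather
than methodological reasons. Indicator columns count as independent features
everywhere downstream.

An explicit `positive_label` is required whenever the raw outcome is not
already coded {0, 1}: outcome files do not say which level is the event, and
silently guessing (e.g., alphabetically) would flip sensitivity.

## Importance scorers

All scorers share one contract: fit on (X, y), produce one finite
non-negative score per column. Conventions that were genuinely open and how
they were fixed:

* **OLS** (`ols_abs_coef`): |coefficient| of a joint least-squares fit of
  the 0/1 outcome on all features, intercept excluded. On rank-deficient
  tables (p > n) the minimum-norm solution is used — the standard
  pseudoinverse convention, recorded in result metadata. The regression-on-
  0/1 reading is used because the cited importance is the linear-model
  coefficient, not a classification margin.
* **LASSO** (`lasso_abs_coef`): coordinate descent at α = 0.01 under the
  scikit-learn objective (1/2n)‖y − Xw‖² + α‖w‖₁, max_iter = 10 000 (ten
  times the library default) so convergence is numerical, not hoped for;
  non-convergence is recorded in metadata as a flag, never raised.
* **Random forest** (`forest_impurity`): 100 trees, class-weight balancing
  on (this scorer models a ~13% positive class), mean decrease in Gini
  impurity with the library's normalization (scores sum to 1 when any split
  occurred). The only scorer with irreducible seed dependence.
* **Gradient-boosted trees** (`gbt_gain`): binary logistic objective,
  default hyperparameters, the booster's default importance — per-split
  average gain, normalized; a never-split feature scores exactly 0. With no
  subsampling the greedy split search is seed-invariant, so rankings are
  identical across seeds even though the scorer is formally stochastic.
* **PCA** (`pca_loading_sum`): columns are mean-centered (not scaled);
  score(f) = Σ_c |loading of f on component c| over all components carrying
  variance. "All" resolves to min(n − 1, p) — centered data admit at most
  n − 1 nonzero components — and components with zero singular value are
  excluded because their loading directions are an arbitrary basis of the
  null space (this also makes a constant column score exactly 0, as the
  zero-centered-vector argument demands). The outcome is never read.
* **Variance** (`variance`): sample variance, denominator n − 1. The 1/n
  convention would rescale every score by the same factor, so rankings are
  identical either way; the test suite asserts the ranking-relevant
  properties rather than the constant.
* **Spearman** (`spearman_abs`): |Pearson correlation of average-rank
  transforms|, vectorized over columns; a constant feature scores 0 by
  convention. Cross-checked against `scipy.stats.spearmanr` in tests.

`variance` and `spearman_abs` carry a declared `univariate` flag; user
scorers registered via `register_scorer` declare theirs.

## Perturbation protocol and strict consistency

From the full table compute a top-k ranking (k = 20 by default). Remove the
top-m features (m = 1 by default) *of that original ranking jointly*, re-run
the identical scorer (same hyperparameters, same seed) on the reduced table,
and re-rank. The verdict is **Consistent** iff original positions m+1…k
equal perturbed positions 1…k−m element-wise. Diagnostics report the first
diverging position, the symmetric set difference of the windows, and whether
the common features preserve relative order.

Conventions that needed fixing:

* Joint (not iterative) removal at depth m: the depth-m probe asks about a
  subset of the *initial* ranking; an iterative mode is available behind a
  flag for exploration and coincides with joint removal for univariate
  scorers.
* The perturbed ranking is computed to full length k and compared on its
  first k − m entries; this reproduces the two-column report layout where
  the perturbed column is a full ranking.
* Stochastic scorers reuse the same seed pre- and post-removal, isolating
  the perturbation effect from sampling noise.
* All-tied degenerate tables remain well-defined: the tie rule orders by
  original column index, which feature removal preserves, so univariate
  scorers stay Consistent even there.

The univariate-invariance property — Consistent for every table, every k,
every m < k — is a theorem for univariate scorers (each surviving score is
bit-identical after removal, and the tie key is preserved), and the suite
verifies it on hundreds of randomized tables with and without heavy ties.

Jaccard and positional-agreement of the compared windows are emitted as
contrast diagnostics only; a Consistent verdict implies both equal 1.0, but
not conversely.

## Downstream evaluation

Fixed evaluator: a 100-tree random forest at library defaults — in
particular *without* class-weight balancing, since the evaluation isolates
the information content of the selected sets under identical untouched
conditions; the scoring forest's balancing and the evaluator's are separate
switches. For each seed s and fold j of a stratified k-fold split
(per-fold class counts differ by ≤ 1), selection is refit on the training
rows only and the evaluator (randomness driven by s, which also drives the
fold split — one seed per repetition) predicts the held-out fold at the
default 0.5 majority vote. Sensitivity and F1 are set to 0 with a warning
when their denominators vanish, which can happen in minority-poor folds.

Aggregation: the default reports mean and SD over all S × F cells
("flat"), stamped into `aggregation_tag`; a per-seed nesting (fold-mean per
seed, then mean/SD over seeds) is selectable, since the choice of nesting is
a reporting convention rather than part of the method. Dense 1-based ranks
(1 = best, ties share a rank and are flagged) compare methods per metric.

## Synthetic data generator

The generator emulates the statistical shape of a TCGA-style breast-cancer
survival table: 705 samples × 1936 features with 13.3% prevalence by
default. The positive count is exact — `round(prevalence · n)` ones placed
by permutation — not binomial, because prevalence is a design property of
the emulated cohort, not an estimand. Planted structure, in leading-column
order: signal features (standard normal plus `signal_effect` · outcome, a
class-conditional Gaussian shift giving analytically controlled association
and exact counts, in preference to logistic-inverse sampling), high-variance
outcome-independent features (variance multiplied by `variance_boost`),
bit-identical duplicate pairs (the missingness mask is shared within a pair
so duplicates survive imputation bit-identical), equicorrelated blocks
(factor construction: √r·shared + √(1−r)·noise), and pure noise. Modality
prefixes (rs_/cn_/mu_/pp_ at 0.6/0.2/0.1/0.1) affect names and — for mu_
noise features, Bernoulli(0.05) sparse binary — marginal distributions,
never the dependence structure. Missing entries are inserted *before*
preprocessing at `missing_rate` (2% default) so the zero-imputation path is
exercised end-to-end. All randomness flows from one PCG64 generator, so
generation is bit-identical across runs and platforms.

Default magnitudes (chosen once as plausible for this kind of data and kept
fixed): 10 signal features with unit class shift — a moderate effect a rank
filter should find without making every method trivially stable; 10
high-variance distractors at 5× variance — clearly separated from unit-scale
noise so variance ranking has an unambiguous planted answer; 5 duplicate
pairs to probe importance-splitting in correlated designs.

What the generator does **not** emulate: real multi-omics covariance
structure, copy-number segmentation, batch effects, modality-specific
dynamic ranges. Consequently, passing tests show that the *framework*
behaves as specified (verdict logic, invariance, leakage-safety,
determinism) — they do not certify that any particular scorer is stable or
accurate on real cohort data, which must be checked by pointing the CLI at
that data.

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale by design: randomized
invariance sweeps use tables up to 300 × 500, and the end-to-end benchmark
uses a 300 × 200 cohort with 2 seeds × 5 folds — large enough to exhibit
multivariate-scorer instability and class-imbalance effects, small enough
that the whole suite runs in about a minute. The full-scale configuration
(705 × 1936, 10 seeds × 10 folds) is the default of the library API and CLI.

Tolerances: hand-computed oracles are asserted to 1e-9; bit-identity is
asserted where the design promises it (univariate locality, determinism,
report bytes). Zero singular values in PCA are detected at a relative 1e-12
threshold. Reports contain no timestamps, making determinism directly
testable at the byte level; run metadata records a semantic config hash
(presentation fields excluded) and library versions, since two scorers defer
to implementation-default importance measures.

## Known limitations

* Consistency is binary by design; it does not grade *how* unstable an
  Inconsistent method is beyond the recorded diagnostics.
* Row-resampling stability (bootstrap/subsample), Kuncheva-type indices,
  SVM/deep-learning attribution methods and time-to-event outcomes are out
  of scope.
* The downstream evaluator is fixed on purpose; results say nothing about
  other classifier families.
* OLS "tied" coefficients on exactly duplicated columns agree only to
  floating-point round-off (minimum-norm splitting), so exact-tie behavior
  is guaranteed only for scorers whose per-column computation is identical
  (variance, Spearman) or exactly symmetric (PCA on identical columns).
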