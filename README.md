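# rankstab

Stability auditing of feature-importance rankings for high-dimensional
tabular biomedicine.

## The problem

In multi-omics outcome modeling (e.g., predicting vital status from a
samples × features table mixing expression, copy-number, mutation and
phosphoprotein measurements), a model's feature-importance ranking is often
read as a list of candidate biomarkers. But high predictive accuracy does not
guarantee that this ranking is stable: for many popular methods, removing a
*single* feature — the method's own top-ranked one — and re-running the
method reshuffles the rest of the list. A ranking that collapses under the
smallest meaningful perturbation is capturing noise- or model-specific
structure, not robust signal.

`rankstab` packages this audit as a reusable benchmark:

* **Seven importance scorers** behind one estimator contract:
  `ols_abs_coef` and `lasso_abs_coef` (|β̂| of linear / L1-penalized
  regression), `forest_impurity` (random-forest mean decrease in Gini
  impurity), `gbt_gain` (gradient-boosted-tree gain), `pca_loading_sum`
  (Σ_c |loading| over all principal components), `variance` (feature-wise
  sample variance, i.e. highly-variable-feature selection) and
  `spearman_abs` (|ρ| with the outcome, average ranks for ties).
* **A strict order-consistency criterion.** With top-*k* ranking
  r = (f₁, …, f_k), remove f₁…f_m, re-score, re-rank. The method is
  **Consistent** iff the original positions m+1…k equal the perturbed
  positions 1…k−m *element-wise* — a uniform rank shift. Any substitution
  or reordering is **Inconsistent**. Ties are broken deterministically by
  original column order, so verdicts are reproducible. Jaccard overlap of
  the same windows is reported as a contrast diagnostic: it stays at 1.0
  under reorderings the strict criterion flags.
* **A leakage-safe downstream harness.** Each scorer's top-k set is scored
  by a fixed 100-tree random-forest evaluator under stratified k-fold CV
  repeated over seeds, with selection *recomputed inside every training
  fold*; per-fold confusion counts yield accuracy, sensitivity
  (TP/(TP+FN), positive = deceased class) and binary F1 (2TP/(2TP+FP+FN)).
* **A synthetic multi-omics-like generator** with planted ground truth
  (outcome-associated features, high-variance distractors, duplicated
  columns, correlated blocks, sparse-binary mutation-like noise, missing
  entries), so the whole framework is testable without any download.

A key structural fact the test suite proves by property testing: *univariate*
scorers (`variance`, `spearman_abs`) are Consistent on **every** table at
every perturbation depth, because each feature's score depends only on its
own column — removing other features cannot change the relative order of the
survivors. Multivariate scorers carry no such guarantee.

## Worked example

```python
from rankstab import (SyntheticSpec, generate, run_perturbation, ScorerConfig,
                      evaluate_selector, EvalConfig)

spec = SyntheticSpec(n_samples=300, n_features=200, n_signal=8, signal_effect=1.0,
                     n_high_variance=5, n_duplicate_pairs=3, seed=0)
table, truth = generate(spec)

for scorer_id in ("forest_impurity", "spearman_abs"):
    report = run_perturbation(table, scorer_id, ScorerConfig(seed=0), k=20, m=1)
    print(scorer_id, report.verdict.label, report.contrast_metrics)

metrics = evaluate_selector(table, "spearman_abs",
                            eval_config=EvalConfig(k=20, n_folds=5, seeds=(0, 1)))
```

Output:

```
table: 300 x 200, 40 positives
forest_impurity: Inconsistent (Jaccard 0.41, positional agreement 0.21)
spearman_abs: Consistent (Jaccard 1.00, positional agreement 1.00)
spearman_abs top-20 downstream: accuracy 0.9067 ± 0.0225, sensitivity 0.3000 ± 0.1687, F1 0.4368 ± 0.2141
```

Read: after removing its own top feature, the forest's Gini ranking retains
only 41% of its top-20 set and almost none of its ordering, while the
Spearman filter shifts up by exactly one position — and its top-20 set still
carries real signal (sensitivity well above the 13% positive base rate would
give a trivial classifier 0). The ± values are SDs over the seed × fold
cells.

Estimator-style use composes with scikit-learn:

```python
from sklearn.pipeline import Pipeline
from sklearn.ensemble import RandomForestClassifier
from rankstab import TopKSelector, SpearmanImportance

pipe = Pipeline([("select", TopKSelector(scorer=SpearmanImportance(), k=20)),
                 ("clf", RandomForestClassifier(n_estimators=100, random_state=0))])
```

## Command line

```bash
rankstab synth --seed 0 --out table.csv --truth-out truth.json   # generate data
rankstab stability --input table.csv --scorer variance --k 20 --m 1
rankstab eval --input table.csv --scorer spearman_abs
rankstab run --config benchmark.yaml                             # full benchmark
```

`run` writes one side-by-side rankings table per scorer ("Ranking (Original
Set)" vs "Ranking (W/O Top 1)", with "―" in the first perturbed cell), a
per-cell CSV, and an aggregate comparison table with consistency labels,
mean ± SD metrics and dense ranks. Reports carry no timestamps: identical
configurations produce byte-identical files. Real data is supplied as a
delimited table with a binary outcome column (default name `vital.status`;
map the positive level explicitly via `--positive-label`).

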