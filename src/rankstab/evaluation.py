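"""Downstream predictive evaluation of selected feature sets.

Each scorer's top-k feature set is assessed with one fixed evaluator — a
random-forest classifier at library defaults — under stratified k-fold
cross-validation repeated over several seeds. Feature selection is recomputed
*inside every training fold*, so held-out rows never influence which features
the evaluator sees (leakage-safe nested selection). Per-(seed, fold) confusion
counts yield accuracy, sensitivity (recall of the positive / deceased class)
and binary F1; aggregates report mean and SD.

The evaluator forest deliberately does NOT apply class-weight balancing (the
importance-scoring forest does): the evaluation isolates the intrinsic
information content of the selected feature sets with no reweighting,
resampling or threshold optimization. Both switches are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .scorers import ScorerConfig, get_scorer
from .stability import rank_top_k
from .table import FeatureTable


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation settings for the downstream evaluator.

    Defaults follow the study design this harness implements: top-20 feature
    sets, stratified 10-fold CV repeated over 10 seeds, a 100-tree forest at
    library defaults. ``aggregation`` chooses the mean/SD nesting: "flat"
    pools all seeds x folds cells; "per_seed" first averages within each seed,
    then takes mean/SD over the per-seed means.
    """

    k: int = 20
    n_folds: int = 10
    seeds: tuple[int, ...] = tuple(range(10))
    evaluator_trees: int = 100
    evaluator_class_weight_balanced: bool = False
    aggregation: str = "flat"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        if self.aggregation not in ("flat", "per_seed"):
            raise ValueError("aggregation must be 'flat' or 'per_seed'")


@dataclass
class EvalCell:
    """One (seed, fold) evaluation: confusion counts, metrics, selected set."""

    seed: int
    fold: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    f1: float
    selected: tuple[str, ...]


@dataclass
class EvalMetrics:
    """Per-cell records plus mean ± SD aggregates of the three metrics."""

    scorer_id: str
    per_cell: list[EvalCell]
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    f1_mean: float
    f1_sd: float
    aggregation_tag: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seed": c.seed,
                    "fold": c.fold,
                    "TP": c.tp,
                    "FP": c.fp,
                    "TN": c.tn,
                    "FN": c.fn,
                    "accuracy": c.accuracy,
                    "sensitivity": c.sensitivity,
                    "f1": c.f1,
                }
                for c in self.per_cell
            ]
        )


def stratified_folds(outcome: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0-based fold id per sample).

    Per-fold counts of each class differ by at most one across folds, and the
    assignment is a pure function of (outcome, n_folds, seed).
    """
    outcome = np.asarray(outcome)
    n = outcome.shape[0]
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n_samples={n}")
    classes, counts = np.unique(outcome, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present for stratification")
    if n_folds > counts.min():
        warnings.warn(
            f"n_folds={n_folds} exceeds the minority class count {counts.min()}; "
            "some folds will lack minority samples",
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), outcome)):
        assignment[test_idx] = fold
    return assignment


def _cell_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int, float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    if tp + fn == 0:
        warnings.warn("no positive samples in fold; sensitivity set to 0", stacklevel=3)
        sensitivity = 0.0
    else:
        sensitivity = tp / (tp + fn)
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("degenerate F1 denominator; F1 set to 0", stacklevel=3)
        f1 = 0.0
    else:
        f1 = 2 * tp / denom
    return tp, fp, tn, fn, accuracy, sensitivity, f1


def evaluate_selector(
    table: FeatureTable,
    scorer_id: str,
    scorer_config: ScorerConfig | None = None,
    eval_config: EvalConfig | None = None,
) -> EvalMetrics:
    """Leakage-safe repeated stratified CV of a scorer's top-k feature set.

    For every seed s and fold j the scorer is fitted on the training rows
    only; its top-k features (tie-broken by the table's frozen column order)
    feed a fresh evaluator forest whose randomness — like the fold split —
    is driven by s. The held-out fold is predicted at the default majority
    vote threshold.
    """
    scorer_config = scorer_config or ScorerConfig()
    eval_config = eval_config or EvalConfig()
    cells: list[EvalCell] = []
    for s in eval_config.seeds:
        assignment = stratified_folds(table.outcome, eval_config.n_folds, s)
        for j in range(eval_config.n_folds):
            train_idx = np.flatnonzero(assignment != j)
            test_idx = np.flatnonzero(assignment == j)
            y_train = table.outcome[train_idx]
            if len(np.unique(y_train)) < 2:
                raise ValueError(f"training fold has a single class (seed={s}, fold={j})")
            train_table = table.take_rows(train_idx)
            result = get_scorer(scorer_id, scorer_config).score_table(train_table)
            ranking = rank_top_k(result, eval_config.k, table.column_order)
            selected = tuple(ranking.ordered_features)
            cols = [table.feature_names.index(f) for f in selected]
            clf = RandomForestClassifier(
                n_estimators=eval_config.evaluator_trees,
                class_weight="balanced" if eval_config.evaluator_class_weight_balanced else None,
                random_state=s,
            )
            clf.fit(table.values[np.ix_(train_idx, cols)], y_train)
            y_pred = clf.predict(table.values[np.ix_(test_idx, cols)])
            tp, fp, tn, fn, acc, sens, f1 = _cell_metrics(table.outcome[test_idx], y_pred)
            cells.append(EvalCell(s, j, tp, fp, tn, fn, acc, sens, f1, selected))

    def aggregate(metric: str) -> tuple[float, float]:
        values = np.array([getattr(c, metric) for c in cells], dtype=float)
        if eval_config.aggregation == "per_seed":
            values = np.array(
                [values[[i for i, c in enumerate(cells) if c.seed == s]].mean()
                 for s in eval_config.seeds]
            )
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return float(values.mean()), sd

    acc_m, acc_s = aggregate("accuracy")
    sens_m, sens_s = aggregate("sensitivity")
    f1_m, f1_s = aggregate("f1")
    tag = (
        "flat mean/SD over all seed x fold cells"
        if eval_config.aggregation == "flat"
        else "mean/SD over per-seed fold means"
    )
    return EvalMetrics(
        scorer_id=scorer_id,
        per_cell=cells,
        accuracy_mean=acc_m,
        accuracy_sd=acc_s,
        sensitivity_mean=sens_m,
        sensitivity_sd=sens_s,
        f1_mean=f1_m,
        f1_sd=f1_s,
        aggregation_tag=tag,
    )


def rank_methods(
    metrics_by_method: Mapping[str, EvalMetrics],
    verdicts: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Comparison table with dense 1-based ranks per metric (1 = best).

    Ties receive the same rank (noted in the ``ties`` column); the optional
    consistency labels are merged in verbatim, never re-derived.
    """
    if len(metrics_by_method) < 2:
        raise ValueError("at least two methods are required for ranking")
    rows = []
    for scorer_id, m in metrics_by_method.items():
        rows.append(
            {
                "method": scorer_id,
                "consistency": (verdicts or {}).get(scorer_id, ""),
                "accuracy_mean": m.accuracy_mean,
                "accuracy_sd": m.accuracy_sd,
                "sensitivity_mean": m.sensitivity_mean,
                "sensitivity_sd": m.sensitivity_sd,
                "f1_mean": m.f1_mean,
                "f1_sd": m.f1_sd,
            }
        )
    frame = pd.DataFrame(rows)
    tie_notes = []
    for metric in ("accuracy", "sensitivity", "f1"):
        ranks = frame[f"{metric}_mean"].rank(method="dense", ascending=False).astype(int)
        frame[f"{metric}_rank"] = ranks
        if ranks.duplicated().any():
            tie_notes.append(metric)
    frame["ties"] = ", ".join(tie_notes) if tie_notes else ""
    return frame.sort_values("accuracy_rank", kind="stable").reset_index(drop=True)
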