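"""Feature-importance scorers behind one uniform estimator contract.

Seven scoring methods, spanning three families:

* supervised learning — ordinary least squares (|coefficient|), LASSO
  (|coefficient| at a mild penalty), random-forest Gini importance,
  gradient-boosted-tree gain importance;
* unsupervised learning — PCA loading sums (sum of |loading| over all
  components), highly-variable-feature selection (feature-wise variance);
* statistical filtering — absolute Spearman rank correlation with the outcome.

Each scorer is a scikit-learn style estimator: ``fit(X, y)`` sets
``importances_`` (one non-negative finite score per column), and works inside
pipelines via :class:`TopKSelector`. ``score_table`` adapts a
:class:`~rankstab.table.FeatureTable` and returns an
:class:`ImportanceResult` whose scores are keyed by feature name.

Variance and Spearman are *univariate*: the score of a feature depends only on
its own column (and, for Spearman, the outcome), which is what makes their
rankings provably invariant under removal of other features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.utils.validation import check_array

from .table import FeatureTable


@dataclass(frozen=True)
class ScorerConfig:
    """Hyperparameters shared across the scorer registry.

    lasso_alpha is the L1 penalty of the LASSO scorer (mild by default so the
    model retains enough active coefficients to rank), lasso_max_iter is
    raised well above the library default to guarantee coordinate-descent
    convergence on wide tables, n_trees sizes the forest scorer,
    class_weight_balanced applies inverse-frequency class weights in the
    forest scorer (the downstream evaluator forest has its own switch), and
    seed drives the stochastic scorers only.
    """

    lasso_alpha: float = 0.01
    lasso_max_iter: int = 10_000
    n_trees: int = 100
    class_weight_balanced: bool = True
    n_components: int | str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lasso_alpha <= 0:
            raise ValueError("lasso_alpha must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ImportanceResult:
    """Per-feature non-negative scores from one scorer, plus determinism info."""

    scorer_id: str
    scores: dict[str, float]
    deterministic: bool
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.array(list(self.scores.values()), dtype=float)
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("all importance scores must be finite and >= 0")


def _validate(X, y=None, *, min_samples: int = 1, require_outcome: bool = False):
    X = check_array(X, dtype=np.float64, ensure_min_samples=min_samples)
    if X.shape[1] < 1:
        raise ValueError("at least one feature column is required")
    if y is None:
        if require_outcome:
            raise ValueError("this scorer requires the outcome vector y")
        return X, None
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    return X, y


class BaseImportanceScorer(BaseEstimator):
    """Common surface: ``fit`` sets ``importances_`` aligned to columns of X."""

    scorer_id: str = ""
    deterministic: bool = True
    univariate: bool = False
    uses_outcome: bool = True

    def fit(self, X, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def score_table(self, table: FeatureTable) -> ImportanceResult:
        """Fit on a FeatureTable and return name-keyed scores."""
        y = table.outcome if self.uses_outcome else None
        self.fit(table.values, y)
        seed = getattr(self, "seed", None) if not self.deterministic else None
        return ImportanceResult(
            scorer_id=self.scorer_id,
            scores=dict(zip(table.feature_names, map(float, self.importances_))),
            deterministic=self.deterministic,
            seed=seed,
            metadata=dict(getattr(self, "fit_metadata_", {})),
        )

    def _check_two_classes(self, y: np.ndarray) -> None:
        if len(np.unique(y)) < 2:
            raise ValueError(f"{self.scorer_id}: both outcome classes must be present")


class OLSImportance(BaseImportanceScorer):
    """|coefficient| of an ordinary least-squares fit of the outcome on all features.

    On rank-deficient tables (p > n, the typical multi-omics shape) the fit is
    the minimum-norm least-squares solution, which is the pseudoinverse
    convention the underlying LAPACK ``gelsd`` driver provides.
    """

    scorer_id = "ols_abs_coef"

    def fit(self, X, y=None):
        X, y = _validate(X, y, min_samples=2, require_outcome=True)
        model = LinearRegression().fit(X, y)
        self.importances_ = np.abs(model.coef_)
        self.fit_metadata_ = {"solution": "minimum_norm_lstsq", "intercept_excluded": True}
        self.n_features_in_ = X.shape[1]
        return self


class LassoImportance(BaseImportanceScorer):
    """|coefficient| of an L1-penalized least-squares fit (coordinate descent)."""

    scorer_id = "lasso_abs_coef"

    def __init__(self, alpha: float = 0.01, max_iter: int = 10_000):
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X, y = _validate(X, y, min_samples=2, require_outcome=True)
        model = Lasso(alpha=self.alpha, max_iter=self.max_iter)
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        self.importances_ = np.abs(model.coef_)
        self.fit_metadata_ = {"alpha": self.alpha, "converged": converged}
        self.n_features_in_ = X.shape[1]
        return self


class ForestImportance(BaseImportanceScorer):
    """Mean decrease in Gini impurity from a random-forest classifier.

    The only scorer here with irreducible stochasticity: bootstrap resampling
    and per-split feature subsampling depend on ``seed``. Importances follow
    the library's normalization (they sum to 1 whenever any split occurred).
    """

    scorer_id = "forest_impurity"
    deterministic = False

    def __init__(self, n_trees: int = 100, class_weight_balanced: bool = True, seed: int = 0):
        self.n_trees = n_trees
        self.class_weight_balanced = class_weight_balanced
        self.seed = seed

    def fit(self, X, y=None):
        X, y = _validate(X, y, require_outcome=True)
        self._check_two_classes(y)
        model = RandomForestClassifier(
            n_estimators=self.n_trees,
            class_weight="balanced" if self.class_weight_balanced else None,
            random_state=self.seed,
        ).fit(X, y.astype(int))
        self.importances_ = model.feature_importances_
        self.fit_metadata_ = {"importance": "mean_decrease_impurity", "n_trees": self.n_trees}
        self.n_features_in_ = X.shape[1]
        return self


class GBTImportance(BaseImportanceScorer):
    """Gain-based importance from gradient-boosted trees (binary logistic loss).

    Uses the booster's default importance measure: per-split average gain,
    normalized to sum 1 over features that were ever split on; a feature never
    used in any split scores exactly 0. With default hyperparameters there is
    no row or column subsampling, so the greedy split selection — and hence
    the ranking — is identical across seeds.
    """

    scorer_id = "gbt_gain"
    deterministic = False

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y=None):
        from xgboost import XGBClassifier

        X, y = _validate(X, y, require_outcome=True)
        self._check_two_classes(y)
        model = XGBClassifier(
            objective="binary:logistic",
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y.astype(int))
        self.importances_ = np.asarray(model.feature_importances_, dtype=np.float64)
        self.fit_metadata_ = {"importance": "gain (per-split average, normalized)"}
        self.n_features_in_ = X.shape[1]
        return self


class PCALoadingImportance(BaseImportanceScorer):
    """Sum of |loading| over all principal components of the centered matrix.

    Columns are mean-centered but not variance-scaled. "All components" means
    min(n_samples - 1, n_features): centered data admit at most n - 1 nonzero
    components. The outcome is never read. Sign flips of components leave the
    score unchanged by construction.
    """

    scorer_id = "pca_loading_sum"
    uses_outcome = False

    def __init__(self, n_components: int | str = "all"):
        self.n_components = n_components

    def fit(self, X, y=None):
        X, _ = _validate(X, min_samples=2)
        n, p = X.shape
        k = min(n - 1, p) if self.n_components == "all" else int(self.n_components)
        model = PCA(n_components=k, svd_solver="full").fit(X)
        # null-space components (zero singular value) have arbitrary loading
        # directions; only components carrying variance contribute
        sv = model.singular_values_
        carries = sv > (sv.max() * 1e-12 if sv.size and sv.max() > 0 else np.inf)
        self.importances_ = np.abs(model.components_[carries]).sum(axis=0)
        self.fit_metadata_ = {
            "n_components": k,
            "nonzero_components": int(carries.sum()),
            "centered": True,
            "scaled": False,
        }
        self.n_features_in_ = p
        return self


class VarianceImportance(BaseImportanceScorer):
    """Feature-wise sample variance (denominator n - 1): highly-variable selection.

    Rankings are invariant to the 1/(n-1) vs 1/n convention since it is a
    constant factor across features; the sample-variance convention is used.
    """

    scorer_id = "variance"
    univariate = True
    uses_outcome = False

    def fit(self, X, y=None):
        X, _ = _validate(X, min_samples=2)
        self.importances_ = np.var(X, axis=0, ddof=1)
        self.fit_metadata_ = {"ddof": 1}
        self.n_features_in_ = X.shape[1]
        return self


class SpearmanImportance(BaseImportanceScorer):
    """|Spearman rank correlation| of each feature with the binary outcome.

    Computed as the Pearson correlation of average-rank transforms (ties get
    average ranks), vectorized over columns. A constant feature has undefined
    correlation and scores 0 by convention.
    """

    scorer_id = "spearman_abs"
    univariate = True

    def fit(self, X, y=None):
        X, y = _validate(X, y, min_samples=3, require_outcome=True)
        self._check_two_classes(y)
        rx = rankdata(X, axis=0, method="average")
        ry = rankdata(y, method="average")
        rxc = rx - rx.mean(axis=0)
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum(axis=0) * (ryc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (rxc.T @ ryc) / denom
        rho[~np.isfinite(rho)] = 0.0  # constant columns
        self.importances_ = np.abs(rho)
        self.fit_metadata_ = {"ties": "average_ranks", "constant_feature_score": 0.0}
        self.n_features_in_ = X.shape[1]
        return self


class FunctionScorer(BaseImportanceScorer):
    """Adapter registering a user function (FeatureTable -> name->score map)."""

    def __init__(self, func: Callable[[FeatureTable], Mapping[str, float]],
                 scorer_id: str, univariate: bool = False, uses_outcome: bool = True):
        self.func = func
        self.scorer_id = scorer_id
        self.univariate = univariate
        self.uses_outcome = uses_outcome

    def fit(self, X, y=None):
        raise NotImplementedError("FunctionScorer works on FeatureTable via score_table")

    def score_table(self, table: FeatureTable) -> ImportanceResult:
        scores = dict(self.func(table))
        if set(scores) != set(table.feature_names):
            raise ValueError(f"{self.scorer_id}: scores must cover exactly the table's features")
        return ImportanceResult(
            scorer_id=self.scorer_id,
            scores={k: float(v) for k, v in scores.items()},
            deterministic=True,
        )


_BUILTIN: dict[str, type[BaseImportanceScorer]] = {
    cls.scorer_id: cls
    for cls in (
        OLSImportance,
        LassoImportance,
        ForestImportance,
        GBTImportance,
        PCALoadingImportance,
        VarianceImportance,
        SpearmanImportance,
    )
}
_REGISTRY: dict[str, Callable[[ScorerConfig], BaseImportanceScorer]] = {}

SCORER_IDS = tuple(_BUILTIN)


def get_scorer(scorer_id: str, config: ScorerConfig | None = None) -> BaseImportanceScorer:
    """Build a scorer instance from the registry, applying the shared config."""
    config = config or ScorerConfig()
    if scorer_id in _REGISTRY:
        return _REGISTRY[scorer_id](config)
    if scorer_id not in _BUILTIN:
        raise KeyError(f"unknown scorer {scorer_id!r}; available: {sorted(set(SCORER_IDS) | set(_REGISTRY))}")
    cls = _BUILTIN[scorer_id]
    if cls is LassoImportance:
        return LassoImportance(alpha=config.lasso_alpha, max_iter=config.lasso_max_iter)
    if cls is ForestImportance:
        return ForestImportance(
            n_trees=config.n_trees,
            class_weight_balanced=config.class_weight_balanced,
            seed=config.seed,
        )
    if cls is GBTImportance:
        return GBTImportance(seed=config.seed)
    if cls is PCALoadingImportance:
        return PCALoadingImportance(n_components=config.n_components)
    return cls()


def register_scorer(
    scorer_id: str,
    func: Callable[[FeatureTable], Mapping[str, float]],
    *,
    univariate: bool = False,
    uses_outcome: bool = True,
) -> None:
    """Register a user-supplied scorer addressable by id (CLI and config)."""
    if scorer_id in _BUILTIN:
        raise ValueError(f"cannot shadow built-in scorer {scorer_id!r}")
    _REGISTRY[scorer_id] = lambda config: FunctionScorer(
        func, scorer_id, univariate=univariate, uses_outcome=uses_outcome
    )


def is_univariate(scorer_id: str, config: ScorerConfig | None = None) -> bool:
    return get_scorer(scorer_id, config).univariate


def score_ols(table: FeatureTable) -> ImportanceResult:
    return OLSImportance().score_table(table)


def score_lasso(table: FeatureTable, config: ScorerConfig | None = None) -> ImportanceResult:
    return get_scorer("lasso_abs_coef", config).score_table(table)


def score_forest_impurity(table: FeatureTable, config: ScorerConfig | None = None) -> ImportanceResult:
    return get_scorer("forest_impurity", config).score_table(table)


def score_gbt_gain(table: FeatureTable, config: ScorerConfig | None = None) -> ImportanceResult:
    return get_scorer("gbt_gain", config).score_table(table)


def score_pca_loading_sum(table: FeatureTable, config: ScorerConfig | None = None) -> ImportanceResult:
    return get_scorer("pca_loading_sum", config).score_table(table)


def score_variance(table: FeatureTable) -> ImportanceResult:
    return VarianceImportance().score_table(table)


def score_spearman(table: FeatureTable) -> ImportanceResult:
    return SpearmanImportance().score_table(table)
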