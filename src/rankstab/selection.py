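"""Top-k feature selection as a scikit-learn transformer.

:class:`TopKSelector` wraps any registered importance scorer and keeps the k
highest-scoring columns, breaking score ties by ascending input column
position — the same deterministic tie policy used by the ranking protocol.
It implements ``SelectorMixin``, so it composes with ``Pipeline`` and model
selection utilities, and is the selection step the downstream evaluation
harness refits inside every training fold.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .scorers import BaseImportanceScorer, ScorerConfig, get_scorer


class TopKSelector(SelectorMixin, BaseEstimator):
    """Select the top-k features under an importance scorer.

    Parameters
    ----------
    scorer : str or BaseImportanceScorer, default "variance"
        Registered scorer id, or a scorer instance (cloned at fit time).
    k : int, default 20
        Number of features to keep (capped at the number of columns).
    scorer_config : ScorerConfig or None
        Hyperparameters applied when ``scorer`` is given by id.

    Attributes
    ----------
    scorer_ : fitted scorer instance
    importances_ : ndarray of per-column scores
    ranking_ : ndarray of selected column indices, best first
    """

    def __init__(self, scorer="variance", k: int = 20, scorer_config: ScorerConfig | None = None):
        self.scorer = scorer
        self.k = k
        self.scorer_config = scorer_config

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = check_array(X, dtype=np.float64)
        if isinstance(self.scorer, BaseImportanceScorer):
            self.scorer_ = clone(self.scorer)
        else:
            self.scorer_ = get_scorer(self.scorer, self.scorer_config)
        self.scorer_.fit(X, y if self.scorer_.uses_outcome else None)
        self.importances_ = np.asarray(self.scorer_.importances_, dtype=np.float64)
        # descending score, ties by ascending input column position
        order = sorted(range(X.shape[1]), key=lambda j: (-self.importances_[j], j))
        self.ranking_ = np.array(order[: min(self.k, X.shape[1])])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask
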