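"""Leave-top-feature-out perturbation and the strict order-consistency criterion.

The protocol: obtain a top-k ranking from the full table, remove the top-m
features of that ranking, re-score the reduced table with identical
configuration and seed, re-rank, and ask whether the surviving ranking is a
*uniform rank shift* of the original — the feature originally ranked (m+1)-th
is now 1st, the (m+2)-th is 2nd, and so on, with no substitutions and no
reordering. A scorer passes ("Consistent") only on an exact element-wise match
of the two windows; any set difference or relative reordering is
"Inconsistent".

This is deliberately stricter than set-overlap stability indices (Jaccard,
Kuncheva): those are blind to reorderings inside the retained set, which is
precisely the instability that matters for interpretation. ``overlap_metrics``
computes Jaccard and a positional-agreement fraction as contrast diagnostics
only.

Ties are resolved deterministically everywhere: scores sort descending, and
equal scores fall back to ascending *original* column order, which feature
removal never renumbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .scorers import ImportanceResult, ScorerConfig, get_scorer
from .table import FeatureTable, drop_features

TIE_POLICY = "stable_by_original_column_order"


@dataclass
class Ranking:
    """Ordered top-k feature list; position 1 is the highest score."""

    ordered_features: list[str]
    k: int
    source_scorer: str
    tie_policy: str = TIE_POLICY
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError("ranking contains duplicate features")

    def __len__(self) -> int:
        return len(self.ordered_features)

    def __getitem__(self, i):
        return self.ordered_features[i]


@dataclass
class ConsistencyVerdict:
    """Consistent/Inconsistent label with divergence diagnostics.

    ``first_divergence`` is the 1-based position (within the compared window)
    of the first mismatch; ``set_difference`` holds features appearing in
    exactly one of the two windows; ``order_preserved`` reports whether the
    features common to both windows keep the same relative order.
    """

    label: str
    first_divergence: int | None
    set_difference: set[str]
    order_preserved: bool

    def __post_init__(self) -> None:
        consistent = (
            not self.set_difference and self.order_preserved and self.first_divergence is None
        )
        if (self.label == "Consistent") != consistent:
            raise ValueError("verdict label inconsistent with its diagnostics")


@dataclass
class StabilityReport:
    """Full record of one perturbation run for one scorer."""

    scorer_id: str
    original_ranking: Ranking
    removed_features: list[str]
    perturbed_ranking: Ranking
    verdict: ConsistencyVerdict
    contrast_metrics: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "scorer_id": self.scorer_id,
            "original_ranking": list(self.original_ranking.ordered_features),
            "removed_features": list(self.removed_features),
            "perturbed_ranking": list(self.perturbed_ranking.ordered_features),
            "verdict": {
                "label": self.verdict.label,
                "first_divergence": self.verdict.first_divergence,
                "set_difference": sorted(self.verdict.set_difference),
                "order_preserved": self.verdict.order_preserved,
            },
            "contrast_metrics": dict(self.contrast_metrics),
            "tie_policy": self.original_ranking.tie_policy,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def side_by_side(self) -> list[tuple[str, str]]:
        """Two-column view: original vs perturbed ranking, the removed
        leading cells of the perturbed column rendered as an em-dash."""
        m = len(self.removed_features)
        left = list(self.original_ranking.ordered_features)
        right = ["―"] * m + list(self.perturbed_ranking.ordered_features)
        rows = max(len(left), len(right))
        left += [""] * (rows - len(left))
        right = right[:rows] + [""] * (rows - len(right))
        return list(zip(left, right))


def rank_top_k(result: ImportanceResult, k: int, column_order: Mapping[str, int]) -> Ranking:
    """Top-k features by descending score; ties broken by original column order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [f for f in result.scores if f not in column_order]
    if missing:
        raise KeyError(f"scored features absent from column_order: {missing[:5]}")
    ordered = sorted(result.scores, key=lambda f: (-result.scores[f], column_order[f]))
    top = ordered[: min(k, len(ordered))]
    return Ranking(
        ordered_features=top,
        k=k,
        source_scorer=result.scorer_id,
        scores={f: result.scores[f] for f in top},
    )


def strict_consistency(original: Ranking, perturbed: Ranking, m: int) -> ConsistencyVerdict:
    """Compare original positions (m+1)..k with perturbed positions 1..(k-m).

    Consistent iff the two windows are element-wise identical (the uniform
    rank shift). Diagnostics always report the first mismatching position,
    the symmetric set difference of the windows, and whether the common
    features preserve their relative order.
    """
    k = len(original)
    if m < 0 or m >= k:
        raise ValueError("require 0 <= m < k")
    window_a = list(original.ordered_features[m:k])
    window_b = list(perturbed.ordered_features[: k - m])
    if len(window_b) < k - m:
        raise ValueError(
            f"perturbed ranking too short: need {k - m} entries, got {len(window_b)}"
        )
    first_divergence = None
    for pos, (a, b) in enumerate(zip(window_a, window_b), start=1):
        if a != b:
            first_divergence = pos
            break
    set_diff = set(window_a) ^ set(window_b)
    common = set(window_a) & set(window_b)
    order_preserved = [f for f in window_a if f in common] == [f for f in window_b if f in common]
    label = "Consistent" if first_divergence is None else "Inconsistent"
    return ConsistencyVerdict(
        label=label,
        first_divergence=first_divergence,
        set_difference=set_diff,
        order_preserved=order_preserved,
    )


def overlap_metrics(original: Ranking, perturbed: Ranking, m: int) -> dict[str, float]:
    """Set-overlap diagnostics on the same compared windows.

    Jaccard index |A∩B|/|A∪B| plus the fraction of positions occupied by the
    same feature. These are *contrast* metrics: Jaccard can be 1.0 while the
    strict verdict is Inconsistent, which is exactly the blindness to
    reordering that motivates the strict criterion.
    """
    k = len(original)
    window_a = list(original.ordered_features[m:k])
    window_b = list(perturbed.ordered_features[: k - m])
    set_a, set_b = set(window_a), set(window_b)
    union = set_a | set_b
    jaccard = len(set_a & set_b) / len(union) if union else 1.0
    n = min(len(window_a), len(window_b))
    positional = (
        sum(a == b for a, b in zip(window_a, window_b)) / n if n else 1.0
    )
    return {"jaccard": jaccard, "positional_agreement": positional}


def run_perturbation(
    table: FeatureTable,
    scorer_id: str,
    config: ScorerConfig | None = None,
    k: int = 20,
    m: int = 1,
    iterative: bool = False,
) -> StabilityReport:
    """Score, remove the top-m features, re-score, and classify consistency.

    By default the top-m features of the ORIGINAL ranking are removed jointly.
    With ``iterative=True`` removal is repeated one feature at a time with
    re-ranking in between (an exploratory mode; the joint convention is the
    protocol's definition). Stochastic scorers reuse the same seed before and
    after removal so the comparison isolates the perturbation itself.
    """
    config = config or ScorerConfig()
    if table.n_features <= k:
        raise ValueError(f"table must have more than k={k} features (got {table.n_features})")
    if not 1 <= m < k:
        raise ValueError("require 1 <= m < k")

    original_result = get_scorer(scorer_id, config).score_table(table)
    original = rank_top_k(original_result, k, table.column_order)

    if iterative:
        removed: list[str] = []
        reduced = table
        current = original
        for _ in range(m):
            top = current.ordered_features[0]
            removed.append(top)
            reduced = drop_features(reduced, {top})
            current = rank_top_k(
                get_scorer(scorer_id, config).score_table(reduced), k, table.column_order
            )
        perturbed = current
    else:
        removed = list(original.ordered_features[:m])
        reduced = drop_features(table, removed)
        perturbed = rank_top_k(
            get_scorer(scorer_id, config).score_table(reduced), k, table.column_order
        )

    verdict = strict_consistency(original, perturbed, m)
    contrast = overlap_metrics(original, perturbed, m)
    return StabilityReport(
        scorer_id=scorer_id,
        original_ranking=original,
        removed_features=removed,
        perturbed_ranking=perturbed,
        verdict=verdict,
        contrast_metrics=contrast,
    )
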