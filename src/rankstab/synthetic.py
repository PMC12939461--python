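"""Synthetic multi-omics-like tables with known ground truth.

The generator emulates the statistical shape of a TCGA-style survival table:
a few hundred samples, a couple of thousand mixed-modality numeric features,
a strongly imbalanced binary outcome (~13.3% positive / deceased), a handful
of planted outcome-associated features, planted high-variance but
outcome-independent features, exactly duplicated column pairs, optionally
correlated feature blocks, pure-noise filler, and missing entries injected
*before* preprocessing so the zero-imputation path is exercised end-to-end.

Signal features use class-conditional Gaussian shifts (positives shifted by
``signal_effect`` standard deviations) rather than logistic-inverse sampling:
this keeps the positive count exact and the feature-outcome association
analytically controlled. Modality prefixes (rs_, cn_, mu_, pp_) affect names
and — for mu_ noise features, which are sparse binary — marginal
distributions, never the dependence structure.

All randomness flows from a single ``numpy.random.default_rng(seed)``
(PCG64), so generation is bit-identical across calls and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import FeatureTable, PreprocessConfig, RawTable, preprocess

DEFAULT_MODALITY_MIX = {"rs_": 0.6, "cn_": 0.2, "mu_": 0.1, "pp_": 0.1}

_MU_SPARSITY = 0.05  # Bernoulli rate for mutation-like sparse binary noise


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror the emulated cohort's shape."""

    n_samples: int = 705
    n_features: int = 1936
    prevalence: float = 0.133
    n_signal: int = 10
    signal_effect: float = 1.0
    n_high_variance: int = 10
    variance_boost: float = 5.0
    n_duplicate_pairs: int = 5
    block_correlation: float = 0.0
    n_blocks: int = 0
    block_size: int = 5
    missing_rate: float = 0.02
    modality_mix: dict = field(default_factory=lambda: dict(DEFAULT_MODALITY_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if round(self.prevalence * self.n_samples) < 1:
            raise ValueError("prevalence * n_samples must be at least 1")
        reserved = (
            self.n_signal
            + self.n_high_variance
            + 2 * self.n_duplicate_pairs
            + self.n_blocks * self.block_size
        )
        if reserved > self.n_features:
            raise ValueError(
                f"planted features ({reserved}) exceed n_features ({self.n_features})"
            )
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.variance_boost <= 1 and self.n_high_variance > 0:
            raise ValueError("variance_boost must exceed 1")


@dataclass
class GroundTruth:
    """Which generated features carry which planted structure."""

    signal_features: list[str]
    high_variance_features: list[str]
    duplicate_pairs: list[tuple[str, str]]
    block_features: list[list[str]]
    noise_features: list[str]
    signal_coefficients: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signal_features": self.signal_features,
            "high_variance_features": self.high_variance_features,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "block_features": self.block_features,
            "noise_features": self.noise_features,
            "signal_coefficients": self.signal_coefficients,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _feature_names(spec: SyntheticSpec) -> list[str]:
    """Prefix assignment by fixed proportion over column positions.

    Counts follow largest-remainder apportionment of the modality mix, and
    prefixes are laid out contiguously in mix order, so the planted leading
    columns take the first prefix (rs_ by default).
    """
    mix = spec.modality_mix
    total = sum(mix.values())
    prefixes = list(mix)
    raw = [mix[pref] / total * spec.n_features for pref in prefixes]
    counts = [int(np.floor(x)) for x in raw]
    remainder_order = sorted(range(len(prefixes)), key=lambda i: counts[i] - raw[i])
    for i in remainder_order[: spec.n_features - sum(counts)]:
        counts[i] += 1
    names, j = [], 0
    for pref, c in zip(prefixes, counts):
        for _ in range(c):
            names.append(f"{pref}F{j:04d}")
            j += 1
    return names


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one table and its ground truth, fully reproducible from the seed.

    The positive count is exactly ``round(prevalence * n_samples)``. Planted
    roles occupy the leading columns in the order signal, high-variance,
    duplicate pairs, correlated blocks; everything after is pure noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    names = _feature_names(spec)

    n_pos = int(round(spec.prevalence * n))
    outcome = np.zeros(n, dtype=np.int64)
    outcome[rng.permutation(n)[:n_pos]] = 1

    values = np.empty((n, p), dtype=np.float64)
    j = 0
    signal_idx = list(range(j, j + spec.n_signal))
    for idx in signal_idx:
        values[:, idx] = rng.standard_normal(n) + spec.signal_effect * outcome
    j += spec.n_signal

    hv_idx = list(range(j, j + spec.n_high_variance))
    for idx in hv_idx:
        values[:, idx] = np.sqrt(spec.variance_boost) * rng.standard_normal(n)
    j += spec.n_high_variance

    dup_pairs_idx = []
    for _ in range(spec.n_duplicate_pairs):
        col = rng.standard_normal(n)
        values[:, j] = col
        values[:, j + 1] = col
        dup_pairs_idx.append((j, j + 1))
        j += 2

    block_idx: list[list[int]] = []
    r = spec.block_correlation
    for _ in range(spec.n_blocks):
        shared = rng.standard_normal(n)
        members = list(range(j, j + spec.block_size))
        for idx in members:
            values[:, idx] = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal(n)
        block_idx.append(members)
        j += spec.block_size

    noise_idx = list(range(j, p))
    for idx in noise_idx:
        if names[idx].startswith("mu_"):
            values[:, idx] = (rng.random(n) < _MU_SPARSITY).astype(np.float64)
        else:
            values[:, idx] = rng.standard_normal(n)

    frame = pd.DataFrame(values, columns=names)
    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        for a, b in dup_pairs_idx:  # keep duplicate pairs bit-identical
            mask[:, b] = mask[:, a]
        frame = frame.mask(mask)
    table = preprocess(
        RawTable(features=frame, outcome=pd.Series(outcome)),
        PreprocessConfig(missing_fill_value=0.0),
    )
    truth = GroundTruth(
        signal_features=[names[i] for i in signal_idx],
        high_variance_features=[names[i] for i in hv_idx],
        duplicate_pairs=[(names[a], names[b]) for a, b in dup_pairs_idx],
        block_features=[[names[i] for i in blk] for blk in block_idx],
        noise_features=[names[i] for i in noise_idx],
        signal_coefficients={names[i]: spec.signal_effect for i in signal_idx},
    )
    return table, truth


def _table(values, names, outcome) -> FeatureTable:
    values = np.asarray(values, dtype=np.float64)
    return FeatureTable(
        values=values,
        feature_names=list(names),
        column_order={f: i for i, f in enumerate(names)},
        outcome=np.asarray(outcome),
    )


def fixture_suite() -> dict[str, FeatureTable]:
    """Small deterministic tables used throughout the test surface.

    * ``spearman_example`` — the 4-sample worked example whose absolute
      Spearman correlation with the outcome is 4/sqrt(20) ≈ 0.8944.
    * ``ols_example`` — single feature [0, 1, 2, 3] against [0, 0, 1, 1];
      the least-squares slope is 0.4.
    * ``pca_uncorrelated`` — two uncorrelated unequal-variance columns, so
      principal components align with the axes and each loading sum is 1.
    * ``separable`` — one binary feature equal to the outcome among noise.
    * ``ties_everywhere`` — every feature identical, every score tied.
    * ``duplicated_columns`` — an informative column duplicated verbatim.
    * ``wide`` — 30 x 300 (p >> n), exercising the rank-deficient OLS path.
    """
    fixtures: dict[str, FeatureTable] = {}
    y4 = np.array([0, 0, 1, 1])
    fixtures["spearman_example"] = _table(
        np.array([[1.0], [2.0], [3.0], [4.0]]), ["x_up"], y4
    )
    fixtures["ols_example"] = _table(
        np.array([[0.0], [1.0], [2.0], [3.0]]), ["x_ols"], y4
    )
    fixtures["pca_uncorrelated"] = _table(
        np.column_stack([2.0 * np.array([1, -1, 1, -1]), np.array([1, 1, -1, -1])]),
        ["wide_axis", "narrow_axis"],
        y4,
    )
    rng = np.random.default_rng(7)
    n = 40
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[: n // 4]] = 1
    sep = np.column_stack([y.astype(float)] + [rng.standard_normal(n) for _ in range(5)])
    fixtures["separable"] = _table(sep, ["f_sep"] + [f"f_noise{i}" for i in range(5)], y)
    ties = np.tile(np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]), (1, 8))
    fixtures["ties_everywhere"] = _table(
        ties, [f"t{i}" for i in range(8)], np.array([0, 1, 0, 1, 0, 1])
    )
    info = rng.standard_normal(n) + 2.0 * y
    dup = np.column_stack([info, info] + [rng.standard_normal(n) for _ in range(4)])
    fixtures["duplicated_columns"] = _table(
        dup, ["dup_a", "dup_b", "n0", "n1", "n2", "n3"], y
    )
    rng_wide = np.random.default_rng(11)
    y_wide = np.zeros(30, dtype=int)
    y_wide[rng_wide.permutation(30)[:8]] = 1
    fixtures["wide"] = _table(
        rng_wide.standard_normal((30, 300)), [f"w{i:03d}" for i in range(300)], y_wide
    )
    return fixtures
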