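"""Samples x features tables with a binary outcome.

The central container is :class:`FeatureTable`: a fully numeric matrix with
named columns, a frozen ``column_order`` map recording each feature's 0-based
position in the *original* (post-encoding) table, and a {0, 1} outcome vector
(1 = positive / deceased class). The frozen column order is the tie-breaking
key for every ranking downstream, and it deliberately survives feature
removal: dropping a column never renumbers the survivors, so rankings of a
perturbed table break ties exactly as the full table would.

Preprocessing follows the minimal convention used for multi-omics survival
tables: numeric missing values are imputed with a constant (zero by default),
categorical columns are one-hot encoded in place (a missing categorical value
yields an all-zero indicator row), and no scaling or normalization is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODALITY_PREFIXES = ("rs_", "cn_", "mu_", "pp_")

DEFAULT_OUTCOME_COLUMN = "vital.status"


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for turning a raw mixed-type table into a :class:`FeatureTable`.

    Parameters
    ----------
    missing_fill_value : float
        Constant imputed into missing numeric entries. Must be finite.
    one_hot : bool
        Whether categorical columns are expanded into indicator columns
        named ``"<col>=<level>"``. If False, categorical columns are an error.
    positive_label : str or None
        Raw outcome level mapped to 1. May be omitted only when the raw
        outcome is already coded {0, 1}.
    """

    missing_fill_value: float = 0.0
    one_hot: bool = True
    positive_label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.missing_fill_value):
            raise ValueError("missing_fill_value must be finite")


@dataclass(frozen=True)
class RawTable:
    """Unprocessed feature columns (file order) plus the raw outcome column."""

    features: pd.DataFrame
    outcome: pd.Series

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def n_columns(self) -> int:
        return self.features.shape[1]


@dataclass
class FeatureTable:
    """Numeric samples x features matrix with a binary outcome.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_features)
        Feature matrix; no missing entries.
    feature_names : list of str
        Unique column names, in the table's current left-to-right order.
    column_order : dict
        feature name -> 0-based column index in the original table. Frozen at
        first preprocessing; feature removal keeps the original indices so the
        deterministic tie policy is unchanged by perturbation.
    outcome : ndarray of shape (n_samples,)
        Values in {0, 1}; 1 is the positive (deceased) class.
    """

    values: np.ndarray
    feature_names: list[str]
    column_order: dict[str, int]
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.outcome = np.asarray(self.outcome)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match values width")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        missing = [f for f in self.feature_names if f not in self.column_order]
        if missing:
            raise ValueError(f"features absent from column_order: {missing}")
        if self.outcome.shape != (self.values.shape[0],):
            raise ValueError("outcome length must match number of rows")
        if not np.all(np.isin(self.outcome, (0, 1))):
            raise ValueError("outcome must contain only 0 and 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite with no missing entries")
        self.outcome = self.outcome.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @staticmethod
    def modality(name: str) -> str:
        """Modality tag derived from the feature-name prefix."""
        for prefix in MODALITY_PREFIXES:
            if name.startswith(prefix):
                return prefix
        return "other"

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def take_rows(self, idx: Sequence[int] | np.ndarray) -> "FeatureTable":
        """Row-subset view (copying), keeping names and column_order intact."""
        idx = np.asarray(idx)
        return FeatureTable(
            values=self.values[idx].copy(),
            feature_names=list(self.feature_names),
            column_order=dict(self.column_order),
            outcome=self.outcome[idx].copy(),
        )

    def to_frame(self, outcome_column: str = DEFAULT_OUTCOME_COLUMN) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, outcome_column, self.outcome)
        return frame


def load_table(path: str | Path, outcome_column: str = DEFAULT_OUTCOME_COLUMN) -> RawTable:
    """Read a delimited table and split off the raw outcome column.

    The delimiter is autodetected from the extension (``.tsv``/``.tab`` are
    tab-separated, anything else comma). A header row is mandatory; duplicate
    column names are a hard error naming the duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="", encoding="utf-8") as handle:
        header = next(csv.reader(handle, delimiter=sep), None)
    if not header:
        raise ValueError(f"{path}: empty file, header row required")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate column names {dupes}")
    if outcome_column not in header:
        raise ValueError(f"{path}: outcome column {outcome_column!r} not found")
    frame = pd.read_csv(path, sep=sep)
    outcome = frame[outcome_column]
    features = frame.drop(columns=[outcome_column])
    return RawTable(features=features, outcome=outcome)


def _encode_outcome(raw: pd.Series, positive_label: str | None) -> np.ndarray:
    if raw.isna().any():
        raise ValueError("outcome column contains missing values")
    levels = pd.unique(raw)
    if pd.api.types.is_numeric_dtype(raw) and set(np.unique(raw)) <= {0, 1}:
        out = raw.to_numpy().astype(np.int64)
        if len(levels) != 2:
            raise ValueError(f"outcome must take exactly two levels, got {sorted(set(out))}")
        return out
    if len(levels) != 2:
        raise ValueError(f"outcome must take exactly two levels, got {len(levels)}: {list(levels)[:5]}")
    if positive_label is None:
        raise ValueError(
            "outcome is not coded {0, 1}; positive_label must name the level mapped to 1 "
            f"(observed levels: {list(levels)})"
        )
    if positive_label not in set(map(str, levels)) and positive_label not in set(levels):
        raise ValueError(f"positive_label {positive_label!r} not among outcome levels {list(levels)}")
    return (raw.astype(str) == str(positive_label)).to_numpy().astype(np.int64)


def preprocess(raw: RawTable, config: PreprocessConfig | None = None) -> FeatureTable:
    """Impute, encode and freeze a raw table into a :class:`FeatureTable`.

    Numeric columns have missing entries replaced by
    ``config.missing_fill_value`` (zero by default). Each categorical column
    with L observed levels becomes L indicator columns ``"<col>=<level>"``
    inserted at the original column's position; a missing categorical entry
    yields an all-zero indicator row. No scaling or normalization is applied.
    ``column_order`` is assigned over the final encoded columns and is the
    canonical order for tie-breaking everywhere downstream.
    """
    config = config or PreprocessConfig()
    outcome = _encode_outcome(raw.outcome, config.positive_label)

    columns: list[tuple[str, np.ndarray]] = []
    for name in raw.features.columns:
        col = raw.features[name]
        if pd.api.types.is_numeric_dtype(col):
            arr = col.to_numpy(dtype=np.float64)
            bad = np.isinf(arr)
            if bad.any():
                raise ValueError(f"column {name!r} contains non-finite values")
            arr = np.where(np.isnan(arr), config.missing_fill_value, arr)
            columns.append((str(name), arr))
        else:
            if not config.one_hot:
                raise ValueError(f"categorical column {name!r} present but one_hot is disabled")
            observed = col.dropna()
            for level in sorted(map(str, pd.unique(observed))):
                indicator = (col.astype("string") == level).fillna(False).to_numpy()
                columns.append((f"{name}={level}", indicator.astype(np.float64)))

    if not columns:
        raise ValueError("table has no feature columns")
    names = [n for n, _ in columns]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"one-hot encoding produced duplicate column names {dupes}")
    values = np.column_stack([arr for _, arr in columns])
    return FeatureTable(
        values=values,
        feature_names=names,
        column_order={n: i for i, n in enumerate(names)},
        outcome=outcome,
    )


def drop_features(table: FeatureTable, names: Iterable[str]) -> FeatureTable:
    """Remove the named columns, preserving order and ORIGINAL column indices.

    Survivors keep their relative order and their original ``column_order``
    entries, so tie-breaking after removal is identical to tie-breaking on the
    full table restricted to the survivors.
    """
    names = set(names)
    unknown = sorted(names - set(table.feature_names))
    if unknown:
        raise KeyError(f"unknown feature names: {unknown}")
    keep = [i for i, f in enumerate(table.feature_names) if f not in names]
    kept_names = [table.feature_names[i] for i in keep]
    return FeatureTable(
        values=table.values[:, keep].copy(),
        feature_names=kept_names,
        column_order={f: table.column_order[f] for f in kept_names},
        outcome=table.outcome.copy(),
    )


def write_table(
    table: FeatureTable, path: str | Path, outcome_column: str = DEFAULT_OUTCOME_COLUMN
) -> None:
    """Round-trip writer: CSV with the outcome as the first column."""
    table.to_frame(outcome_column).to_csv(path, index=False)
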