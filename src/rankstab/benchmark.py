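"""End-to-end benchmark: perturbation stability plus downstream evaluation.

``run_benchmark`` wires the pipeline together — load or generate a table,
run the leave-top-feature-out perturbation for every configured scorer, run
the leakage-safe CV evaluation, and merge everything into one comparison
table with dense ranks and consistency labels. ``render_tables`` writes the
three-table report shape: one side-by-side rankings table per scorer (the
removed leading cell rendered as an em-dash) and the aggregate comparison.

Reports carry no timestamps, so two runs with identical configuration and
seeds produce byte-identical files; run metadata records the config hash,
seeds and library versions instead (two scorers defer to implementation
defaults, so the versions matter for provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .evaluation import EvalConfig, EvalMetrics, evaluate_selector, rank_methods
from .scorers import SCORER_IDS, ScorerConfig
from .stability import StabilityReport, run_perturbation
from .synthetic import SyntheticSpec, generate
from .table import (
    DEFAULT_OUTCOME_COLUMN,
    FeatureTable,
    PreprocessConfig,
    load_table,
    preprocess,
)

logger = logging.getLogger("rankstab")

REPORT_FORMATS = ("csv", "json", "markdown")


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs.

    Exactly one of ``input_path`` (a delimited table on disk) or
    ``synthetic_spec`` must be provided.
    """

    input_path: str | None = None
    outcome_column: str = DEFAULT_OUTCOME_COLUMN
    positive_label: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    scorers: tuple[str, ...] = SCORER_IDS
    scorer_config: ScorerConfig = field(default_factory=ScorerConfig)
    k: int = 20
    m: int = 1
    eval_config: EvalConfig = field(default_factory=EvalConfig)
    output_dir: str = "rankstab_out"
    formats: tuple[str, ...] = ("csv", "json")

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic_spec is None):
            raise ValueError("provide exactly one of input_path or synthetic_spec")
        if not self.scorers:
            raise ValueError("at least one scorer is required")
        if not self.m < self.k:
            raise ValueError(f"perturbation depth m={self.m} must be smaller than k={self.k}")
        unknown = [f for f in self.formats if f not in REPORT_FORMATS]
        if unknown:
            raise ValueError(f"unknown report formats {unknown}; available: {REPORT_FORMATS}")

    def semantic_dict(self) -> dict:
        """Fields that affect results (presentation knobs excluded)."""
        d = {
            "input_path": self.input_path,
            "outcome_column": self.outcome_column,
            "positive_label": self.positive_label,
            "synthetic_spec": asdict(self.synthetic_spec) if self.synthetic_spec else None,
            "scorers": list(self.scorers),
            "scorer_config": asdict(self.scorer_config),
            "k": self.k,
            "m": self.m,
            "eval_config": asdict(self.eval_config),
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BenchmarkResult:
    stability_reports: dict[str, StabilityReport]
    eval_metrics: dict[str, EvalMetrics]
    comparison: pd.DataFrame
    metadata: dict


def _library_versions() -> dict[str, str]:
    import numpy, pandas, scipy, sklearn, xgboost  # noqa: E401

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


def _load_input(config: BenchmarkConfig) -> FeatureTable:
    if config.synthetic_spec is not None:
        table, _ = generate(config.synthetic_spec)
        return table
    raw = load_table(config.input_path, config.outcome_column)
    return preprocess(raw, PreprocessConfig(positive_label=config.positive_label))


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Execute preprocess -> per-scorer perturbation -> per-scorer CV -> ranks."""
    config.validate()
    table = _load_input(config)
    logger.info("table loaded: %d samples x %d features", table.n_samples, table.n_features)

    stability_reports: dict[str, StabilityReport] = {}
    eval_metrics: dict[str, EvalMetrics] = {}
    for scorer_id in config.scorers:
        logger.info("perturbation protocol: %s", scorer_id)
        stability_reports[scorer_id] = run_perturbation(
            table, scorer_id, config.scorer_config, k=config.k, m=config.m
        )
        logger.info("downstream evaluation: %s", scorer_id)
        eval_metrics[scorer_id] = evaluate_selector(
            table, scorer_id, config.scorer_config, config.eval_config
        )

    verdicts = {sid: rep.verdict.label for sid, rep in stability_reports.items()}
    comparison = rank_methods(eval_metrics, verdicts) if len(eval_metrics) >= 2 else None
    metadata = {
        "config": config.semantic_dict(),
        "config_hash": config.config_hash(),
        "library_versions": _library_versions(),
        "n_samples": table.n_samples,
        "n_features": table.n_features,
    }
    return BenchmarkResult(
        stability_reports=stability_reports,
        eval_metrics=eval_metrics,
        comparison=comparison,
        metadata=metadata,
    )


def _rankings_frame(report: StabilityReport) -> pd.DataFrame:
    rows = report.side_by_side()
    return pd.DataFrame(
        rows, columns=["Ranking (Original Set)", f"Ranking (W/O Top {len(report.removed_features)})"]
    )


def _comparison_frame(result: BenchmarkResult) -> pd.DataFrame:
    frame = result.comparison.copy()
    for metric in ("accuracy", "sensitivity", "f1"):
        frame[metric] = [
            f"{m:.4f} ± {s:.4f}"
            for m, s in zip(frame[f"{metric}_mean"], frame[f"{metric}_sd"])
        ]
    cols = [
        "method", "consistency",
        "accuracy", "accuracy_rank",
        "sensitivity", "sensitivity_rank",
        "f1", "f1_rank",
    ]
    return frame[cols]


def render_tables(result: BenchmarkResult, fmt: str, output_dir: str | Path) -> list[Path]:
    """Write per-scorer rankings tables and the aggregate comparison table."""
    if fmt not in REPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; available: {REPORT_FORMATS}")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, stem: str) -> None:
        if fmt == "csv":
            path = outdir / f"{stem}.csv"
            frame.to_csv(path, index=False)
        elif fmt == "markdown":
            path = outdir / f"{stem}.md"
            path.write_text(frame.to_markdown(index=False) + "\n")
        else:
            path = outdir / f"{stem}.json"
            path.write_text(frame.to_json(orient="records", indent=2) + "\n")
        written.append(path)

    for scorer_id, report in result.stability_reports.items():
        emit(_rankings_frame(report), f"rankings_{scorer_id}")
    if result.comparison is not None:
        emit(_comparison_frame(result), "comparison")

    full = {
        "metadata": result.metadata,
        "stability": {sid: rep.to_dict() for sid, rep in result.stability_reports.items()},
        "evaluation": {
            sid: {
                "accuracy_mean": m.accuracy_mean,
                "accuracy_sd": m.accuracy_sd,
                "sensitivity_mean": m.sensitivity_mean,
                "sensitivity_sd": m.sensitivity_sd,
                "f1_mean": m.f1_mean,
                "f1_sd": m.f1_sd,
                "aggregation": m.aggregation_tag,
            }
            for sid, m in result.eval_metrics.items()
        },
    }
    report_path = outdir / "benchmark_report.json"
    report_path.write_text(json.dumps(full, indent=2, sort_keys=True) + "\n")
    written.append(report_path)

    for sid, m in result.eval_metrics.items():
        cell_path = outdir / f"cells_{sid}.csv"
        m.to_frame().to_csv(cell_path, index=False)
        written.append(cell_path)
    return written
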