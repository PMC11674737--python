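"""Dataset loading, result tables and the three experiment modes.

The loader consumes a headered CSV with numeric predictors plus a binary
label column (default ``Mal``), drops identifier columns, and rejects
missing or unparseable cells with errors naming the offending
column/row.  ``run_experiment`` drives the per-classifier pipeline for
the three modes — library defaults, 1-level hyperparameter optimization,
and 2-level joint hyperparameter + feature-subset optimization — and
emits one result row per classifier in the standard report layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, EvaluationFailed, LoaderError
from .codec import CLASSIFIER_IDS, REGISTRY_VERSION
from .evaluation import EvaluationReport, TabularDataset, stratified_kfold
from .imbalance import OversamplerConfig
from .search import NMRSearchCV, evaluate_default

logger = logging.getLogger("nmrtune.io")

__all__ = [
    "load_dataset",
    "save_dataset",
    "write_results",
    "read_results",
    "ExperimentConfig",
    "run_experiment",
    "RESULT_COLUMNS",
]

#: Report layout: classifier, feature count, then metrics.
RESULT_COLUMNS = (
    "Classifier",
    "Number of Features",
    "Accuracy",
    "F1-Score",
    "AUC",
    "Recall",
    "Precision",
)

_DEFAULT_DROP = ("id", "ID", "Id", "iD")


def load_dataset(
    path: str | Path,
    label_column: str = "Mal",
    drop_columns: Sequence[str] | None = None,
) -> TabularDataset:
    """Load a headered CSV into a :class:`TabularDataset`.

    Identifier columns are dropped (case variants of ``id`` by default),
    the label must be binary with both classes present, and any missing
    or non-numeric cell fails loading with a report naming it.
    """
    path = Path(path)
    if not path.exists():
        raise LoaderError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise LoaderError(
            f"label column {label_column!r} not found; columns: {list(frame.columns)}"
        )
    drop = set(drop_columns) if drop_columns is not None else set(_DEFAULT_DROP)
    frame = frame.drop(columns=[c for c in frame.columns if c in drop])

    if frame.isna().any().any():
        bad = {
            col: frame.index[frame[col].isna()].tolist()[:5]
            for col in frame.columns
            if frame[col].isna().any()
        }
        raise LoaderError(f"missing values (column -> first rows): {bad}")

    labels = frame[label_column]
    distinct = sorted(pd.unique(labels).tolist())
    if set(distinct) != {0, 1}:
        raise LoaderError(
            f"label column {label_column!r} must be binary 0/1; found values {distinct}"
        )

    predictors = frame.drop(columns=[label_column])
    for col in predictors.columns:
        coerced = pd.to_numeric(predictors[col], errors="coerce")
        if coerced.isna().any():
            row = int(predictors.index[coerced.isna()][0])
            raise LoaderError(f"column {col!r} has a non-numeric cell at row {row}")
        predictors[col] = coerced

    return TabularDataset(
        X=predictors.to_numpy(dtype=float),
        y=labels.to_numpy(dtype=int),
        feature_names=tuple(predictors.columns),
        label_name=label_column,
    )


def save_dataset(dataset: TabularDataset, path: str | Path) -> None:
    frame = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    frame[dataset.label_name] = dataset.y
    frame.to_csv(path, index=False)


def _report_row(classifier_id: str, report: EvaluationReport) -> dict:
    return {
        "Classifier": classifier_id,
        "Number of Features": report.n_features_used,
        "Accuracy": round(report.accuracy, 4),
        "F1-Score": round(report.f1, 4),
        "AUC": round(report.auc, 4),
        "Recall": round(report.recall, 4),
        "Precision": round(report.precision, 4),
    }


def write_results(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    frame = pd.DataFrame(list(rows) if not isinstance(rows, pd.DataFrame) else rows,
                         columns=list(RESULT_COLUMNS))
    frame.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class ExperimentConfig:
    """One experiment run: mode, classifiers, budgets and seeds.

    Shipped budgets are desk-scale; the full-scale study budget
    (pop_size=1000, epochs=200) is available but long-running.
    """

    mode: str = "default"  # "default" | "optimize_params" | "optimize_params_and_features"
    classifiers: tuple[str, ...] = CLASSIFIER_IDS
    cv: int = 10
    stratified: bool = True
    pop_size: int = 30
    epochs: int = 40
    pb: float = 0.75
    pm: float = 0.1
    oversample: str = "none"
    standardize: str = "per_fold"
    range_overrides: dict | None = None
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("default", "optimize_params", "optimize_params_and_features"):
            raise ConfigurationError(f"unknown experiment mode {self.mode!r}")
        unknown = set(self.classifiers) - set(CLASSIFIER_IDS)
        if unknown:
            raise ConfigurationError(f"unknown classifiers: {sorted(unknown)}")


def _fanout_seed(global_seed: int, index: int) -> int:
    """Deterministic per-classifier seed derived from the global seed."""
    return int((global_seed * 9973 + 7919 * index + 1) % (2**31 - 1))


def run_experiment(config: ExperimentConfig, dataset: TabularDataset) -> pd.DataFrame:
    """Run one experiment mode over all requested classifiers.

    Returns the result table (one row per classifier in the standard
    layout).  When ``output_dir`` is set, also writes ``results.csv``,
    per-classifier best-configuration JSON files, and a run manifest
    recording the config, fanned-out seeds and registry version.
    A classifier whose backend rejects even its default configuration is
    marked failed and the run continues.
    """
    rows: list[dict] = []
    best_configs: dict[str, dict] = {}
    seeds: dict[str, int] = {}

    for i, classifier_id in enumerate(config.classifiers):
        seed = _fanout_seed(config.seed, i)
        seeds[classifier_id] = seed
        oversampler = (
            None
            if config.oversample == "none"
            else OversamplerConfig(method=config.oversample, seed=seed)
        )
        try:
            if config.mode == "default":
                plan = stratified_kfold(dataset.y, config.cv, seed=seed,
                                        stratified=config.stratified)
                report = evaluate_default(
                    dataset, classifier_id, plan,
                    oversampler=oversampler, standardize=config.standardize,
                )
                best_configs[classifier_id] = {"params": {}, "features": "all"}
            else:
                search = NMRSearchCV(
                    classifier=classifier_id,
                    select_features=config.mode == "optimize_params_and_features",
                    pop_size=config.pop_size,
                    epochs=config.epochs,
                    pb=config.pb,
                    pm=config.pm,
                    cv=config.cv,
                    stratified=config.stratified,
                    oversample=config.oversample,
                    standardize=config.standardize,
                    range_overrides=config.range_overrides,
                    random_state=seed,
                )
                search.fit(dataset.X, dataset.y, feature_names=dataset.feature_names)
                report = search.best_report_
                best_configs[classifier_id] = {
                    "params": search.best_params_,
                    "features": [
                        name
                        for name, keep in zip(dataset.feature_names, search.support_)
                        if keep
                    ],
                }
        except EvaluationFailed as exc:
            logger.warning("%s failed: %s", classifier_id, exc)
            rows.append({
                "Classifier": classifier_id,
                "Number of Features": dataset.n_features,
                "Accuracy": float("nan"),
                "F1-Score": float("nan"),
                "AUC": float("nan"),
                "Recall": float("nan"),
                "Precision": float("nan"),
            })
            continue
        rows.append(_report_row(classifier_id, report))

    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(frame, out / "results.csv")
        (out / "best_configs.json").write_text(json.dumps(best_configs, indent=2, default=str))
        manifest = {
            "mode": config.mode,
            "classifiers": list(config.classifiers),
            "cv": config.cv,
            "stratified": config.stratified,
            "pop_size": config.pop_size,
            "epochs": config.epochs,
            "pb": config.pb,
            "pm": config.pm,
            "oversample": config.oversample,
            "standardize": config.standardize,
            "global_seed": config.seed,
            "classifier_seeds": seeds,
            "registry_version": REGISTRY_VERSION,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return frame
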