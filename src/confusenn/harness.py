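"""The shuffle test: predictor degradation across disruption levels.

Given a labeled dataset and any predictor — an in-process callable, a
statistic-threshold oracle, or a directory of prediction files produced by
an external model such as a trained CNN — :func:`run_shuffle_test` applies
every requested shuffle level to the test data, collects predictions at
each level, and computes task metrics (classification: accuracy, confusion
matrix, ROC/AUC for binary tasks; regression: Spearman's r and RMSE).
The per-level decline in performance reveals which population-genetic
features the predictor exploits.

Multiple independently trained predictor instances can be aggregated with
:func:`aggregate_instances`, which reports the mean and an empirical 95%
percentile interval per metric and level.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

from .matrix import HaplotypeMatrix, ShuffleLevel
from .shuffles import battery
from .synthetic import LabeledDataset, OracleClassifier, predict_oracle

logger = logging.getLogger(__name__)

__all__ = [
    "ContractError",
    "DegradationReport",
    "PredictionFiles",
    "evaluate_classifier",
    "evaluate_regressor",
    "run_shuffle_test",
    "aggregate_instances",
    "write_report",
    "read_report",
]

#: Scalar metrics eligible for cross-instance aggregation, per task.
SCALAR_METRICS = {
    "classification": ("accuracy", "no_information_rate", "auc"),
    "regression": ("spearman_r", "rmse"),
}


class ContractError(ValueError):
    """A predictor violated its contract (e.g. wrong prediction count)."""


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_classifier(
    y_true: Sequence,
    y_pred: Sequence,
    scores: Optional[Sequence[float]] = None,
    positive_label=None,
) -> dict:
    """Classification metrics: accuracy, confusion matrix, binary ROC/AUC.

    The confusion matrix has one row per true class and one column per
    predicted class, over the sorted union of observed labels. For binary
    truth with scores supplied, a ROC curve (score-threshold sweep) and
    its trapezoidal AUC are added, treating ``positive_label`` (default:
    the lexicographically larger class) as positive. The no-information
    rate (largest true-class frequency) is reported so degradation toward
    chance is interpretable.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    true_classes = sorted(set(y_true))
    if len(true_classes) < 2:
        raise ValueError("need >= 2 classes present in truth")
    classes = sorted(set(y_true) | set(y_pred))
    conf = skm.confusion_matrix(y_true, y_pred, labels=classes)
    acc = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    counts = np.array([y_true.count(c) for c in classes])
    out = {
        "accuracy": acc,
        "no_information_rate": float(counts.max() / counts.sum()),
        "classes": classes,
        "confusion": conf.tolist(),
    }
    if len(true_classes) == 2:
        if scores is None:
            logger.info("binary task without scores: ROC/AUC omitted")
        else:
            pos = positive_label if positive_label is not None else true_classes[1]
            y_bin = np.array([t == pos for t in y_true], dtype=int)
            fpr, tpr, thr = skm.roc_curve(y_bin, np.asarray(scores, dtype=float))
            out["auc"] = float(skm.auc(fpr, tpr))
            out["roc"] = {
                "fpr": fpr.tolist(),
                "tpr": tpr.tolist(),
                "thresholds": [float(t) for t in thr],
                "positive_label": pos,
            }
    return out


def evaluate_regressor(y_true: Sequence[float], y_pred: Sequence[float]) -> dict:
    """Regression metrics: Spearman's r (average-rank ties) and RMSE.

    Constant truth or constant predictions make the rank correlation
    undefined; it is then reported as 0 with ``degenerate`` set.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) != len(p):
        raise ValueError("lengths differ")
    if len(y) < 3:
        raise ValueError("need >= 3 examples")
    rmse = float(np.sqrt(np.mean((y - p) ** 2)))
    degenerate = bool(np.all(y == y[0]) or np.all(p == p[0]))
    if degenerate:
        r = 0.0
    else:
        r = float(sps.spearmanr(y, p).statistic)
    return {"spearman_r": r, "rmse": rmse, "degenerate": degenerate}


# ---------------------------------------------------------------------------
# Predictor contracts
# ---------------------------------------------------------------------------

class PredictionFiles:
    """Predictions from an external model, one file per shuffle level.

    ``directory`` holds ``<LEVEL>.tsv`` files (e.g. ``IDENTITY.tsv``,
    ``COLUMNS.tsv``), one prediction per line: ``label<TAB>score`` for
    classification, a single real value for regression. This is the
    interoperation route for published CNNs, which live in their own
    code bases: shuffle the test data here, predict there, report here.
    """

    def __init__(self, directory: str):
        self.directory = directory

    def for_level(self, level: ShuffleLevel) -> list:
        path = os.path.join(self.directory, f"{ShuffleLevel(level).name}.tsv")
        if not os.path.exists(path):
            raise ContractError(f"no prediction file for level {ShuffleLevel(level).name}")
        preds = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    preds.append(float(parts[0]))
                else:
                    preds.append((parts[0], float(parts[1])))
        return preds


Predictor = Union[
    Callable[[Sequence[HaplotypeMatrix]], list],
    PredictionFiles,
    OracleClassifier,
]


def _get_predictions(
    predictor: Predictor, matrices: Sequence[HaplotypeMatrix], level: ShuffleLevel
) -> list:
    if isinstance(predictor, OracleClassifier):
        return predict_oracle(predictor, matrices)
    if isinstance(predictor, PredictionFiles):
        return predictor.for_level(level)
    return predictor(matrices)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class DegradationReport:
    """Per-shuffle-level metrics, optionally aggregated over instances.

    ``metrics`` maps level name to the metric dict of
    :func:`evaluate_classifier` / :func:`evaluate_regressor` (for an
    aggregated report, to scalar means). ``instances`` holds per-instance
    metric dicts and ``aggregate`` the mean and empirical 95% percentile
    interval per scalar metric when several predictor instances were run.
    """

    task: str
    levels: list[str]
    metrics: dict
    instances: Optional[list] = None
    aggregate: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "levels": self.levels,
            "metrics": self.metrics,
            "instances": self.instances,
            "aggregate": self.aggregate,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DegradationReport":
        return cls(
            task=d["task"],
            levels=list(d["levels"]),
            metrics=d["metrics"],
            instances=d.get("instances"),
            aggregate=d.get("aggregate"),
            provenance=d.get("provenance", {}),
        )


def run_shuffle_test(
    dataset: LabeledDataset,
    predictor: Predictor,
    levels: Optional[Iterable[ShuffleLevel]] = None,
    master_seed: int = 0,
    positive_label=None,
) -> DegradationReport:
    """Evaluate a predictor on the dataset at every shuffle level.

    IDENTITY is always evaluated first as the baseline. Shuffles are
    applied to the test data only, via :func:`confusenn.shuffles.battery`
    with seeds derived from ``master_seed``, so the whole run is
    deterministic given (dataset, predictor, master_seed).
    """
    if positive_label is None and isinstance(predictor, OracleClassifier):
        # the oracle's score is its raw statistic, oriented toward class_high
        positive_label = predictor.class_high
    if levels is None:
        levels = list(ShuffleLevel)
    levels = [ShuffleLevel(l) for l in levels]
    if ShuffleLevel.IDENTITY in levels:
        levels.remove(ShuffleLevel.IDENTITY)
    levels = [ShuffleLevel.IDENTITY] + levels

    shuffled = battery(dataset.matrices, levels, master_seed)
    metrics: dict[str, dict] = {}
    for level in levels:
        preds = _get_predictions(predictor, shuffled[level], level)
        if len(preds) != len(dataset):
            raise ContractError(
                f"predictor returned {len(preds)} predictions for "
                f"{len(dataset)} examples at level {level.name}"
            )
        if dataset.task == "classification":
            if preds and isinstance(preds[0], tuple):
                labels = [p[0] for p in preds]
                scores = [p[1] for p in preds]
            else:
                labels, scores = list(preds), None
            metrics[level.name] = evaluate_classifier(
                dataset.labels, labels, scores, positive_label=positive_label
            )
        else:
            metrics[level.name] = evaluate_regressor(dataset.labels, preds)
    return DegradationReport(
        task=dataset.task,
        levels=[l.name for l in levels],
        metrics=metrics,
        provenance={
            "dataset": dataset.metadata,
            "master_seed": int(master_seed),
            "levels": [l.name for l in levels],
        },
    )


def aggregate_instances(reports: Sequence[DegradationReport]) -> DegradationReport:
    """Aggregate reports from independently trained predictor instances.

    Per level and scalar metric, reports the mean and the empirical
    2.5/97.5 percentile interval (linear interpolation) across instances.
    Requires at least two reports over the same task and levels.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("aggregate_instances requires >= 2 reports")
    first = reports[0]
    for r in reports[1:]:
        if r.levels != first.levels or r.task != first.task:
            raise ValueError("reports differ in levels or task")
    scalar = SCALAR_METRICS[first.task]
    aggregate: dict[str, dict] = {}
    means: dict[str, dict] = {}
    for level in first.levels:
        aggregate[level] = {}
        means[level] = {}
        for metric in scalar:
            vals = [
                r.metrics[level][metric]
                for r in reports
                if metric in r.metrics[level]
            ]
            if len(vals) != len(reports):
                continue
            vals = np.asarray(vals, dtype=float)
            lo, hi = np.percentile(vals, [2.5, 97.5])
            aggregate[level][metric] = {
                "mean": float(vals.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "interval": "percentile-95",
            }
            means[level][metric] = float(vals.mean())
    return DegradationReport(
        task=first.task,
        levels=list(first.levels),
        metrics=means,
        instances=[r.metrics for r in reports],
        aggregate=aggregate,
        provenance={**first.provenance, "n_instances": len(reports)},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_report(r: DegradationReport, path: str, format: str = "json") -> None:
    """Write a report as JSON (full nested structure; round-trips via
    :func:`read_report`) and/or TSV (one row per level x metric x
    instance, plus aggregate rows)."""
    if format not in ("json", "tsv", "both"):
        raise ValueError(f"unknown format {format!r}")
    base, ext = os.path.splitext(path)
    if format in ("json", "both"):
        with open(path if ext == ".json" else base + ".json", "w") as fh:
            json.dump(r.to_dict(), fh, indent=1)
            fh.write("\n")
    if format in ("tsv", "both"):
        import pandas as pd

        rows = []
        scalar = SCALAR_METRICS[r.task]
        sources = (
            [(str(i), m) for i, m in enumerate(r.instances)]
            if r.instances
            else [("0", r.metrics)]
        )
        for inst, metrics in sources:
            for level in r.levels:
                for metric in scalar:
                    if metric in metrics[level]:
                        rows.append(
                            (level, metric, inst, metrics[level][metric])
                        )
        if r.aggregate:
            for level in r.levels:
                for metric, agg in r.aggregate[level].items():
                    rows.append((level, metric, "aggregate_mean", agg["mean"]))
                    rows.append((level, metric, "aggregate_ci_low", agg["ci_low"]))
                    rows.append((level, metric, "aggregate_ci_high", agg["ci_high"]))
        pd.DataFrame(
            rows, columns=["level", "metric", "instance", "value"]
        ).to_csv(path if ext == ".tsv" else base + ".tsv", sep="\t", index=False)


def read_report(path: str) -> DegradationReport:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return DegradationReport.from_dict(json.load(fh))
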