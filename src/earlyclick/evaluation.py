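"""Classification performance and feature importance, failure as positive.

All confusion-based metrics treat failure (label 1) as the positive class.
A row is classified as failure when its predicted failure probability
strictly exceeds the discrimination threshold (default .50). Rates with a
zero denominator are reported as missing; the φ coefficient — the Pearson
correlation between the observed and predicted binary vectors — is set to
0 when any marginal is zero. AUC uses the rank (Mann–Whitney) formulation
with midranks for ties.

Feature importance is gain-based: per trained ensemble, each feature's
average split gain, normalized so the importances of one fold sum to 1;
across outer folds the mean, sd, and maximum are reported, with a flag for
features whose gain exceeded 0.05 in at least one fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import FoldResult

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "metrics",
    "auc",
    "feature_importance",
    "aggregate_report",
    "evaluate_folds",
]

GAIN_REPORT_THRESHOLD = 0.05
METRIC_NAMES = ("auc", "phi", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with failure as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.50) -> ConfusionCounts:
    """Dichotomize predicted failure probabilities and cross-tabulate.

    Predicted failure iff probability strictly exceeds the threshold, so a
    probability of exactly .50 is classified as success.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing")
        return math.nan
    return num / den


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and φ from a confusion matrix."""
    phi_den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    phi = 0.0 if phi_den == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(phi_den)
    return {
        "sensitivity": _rate(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _rate(c.tn, c.tn + c.fp, "specificity"),
        "ppv": _rate(c.tp, c.tp + c.fp, "PPV"),
        "npv": _rate(c.tn, c.tn + c.fn, "NPV"),
        "phi": phi,
    }


def auc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Probability a random failure outranks a random success (ties half)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def feature_importance(fold_models: Sequence[FoldResult]) -> pd.DataFrame:
    """Gain importance per feature, aggregated across outer folds.

    Per fold, each feature's average split gain is normalized so the fold's
    importances sum to 1; a feature unused in a fold's trees scores 0.
    Returns a table with mean, sd and max across folds plus a ``reported``
    flag marking features whose gain exceeded 0.05 in at least one fold.
    """
    if not fold_models:
        raise ValueError("at least one trained fold model is required")
    all_features: list[str] = []
    for fr in fold_models:
        for name in fr.feature_names:
            if name not in all_features:
                all_features.append(name)
    per_fold = pd.DataFrame(0.0, index=all_features, columns=range(len(fold_models)))
    for k, fr in enumerate(fold_models):
        booster = fr.model.get_booster()
        gains = booster.get_score(importance_type="gain")
        total = sum(gains.values())
        if total > 0:
            for name, g in gains.items():
                per_fold.loc[name, k] = g / total
    table = pd.DataFrame(
        {
            "mean_gain": per_fold.mean(axis=1),
            "sd_gain": per_fold.std(axis=1, ddof=1) if len(fold_models) > 1 else 0.0,
            "max_gain": per_fold.max(axis=1),
        }
    )
    table["reported"] = table["max_gain"] > GAIN_REPORT_THRESHOLD
    return table.sort_values("mean_gain", ascending=False)


@dataclass
class EvaluationReport:
    """Per-fold and aggregated metrics plus window descriptives."""

    per_fold: pd.DataFrame  # one row per outer fold, columns METRIC_NAMES
    summary: pd.DataFrame  # index METRIC_NAMES, columns mean/sd
    descriptives: dict
    importance: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "summary": {
                m: {"mean": self.summary.loc[m, "mean"], "sd": self.summary.loc[m, "sd"]}
                for m in self.summary.index
            },
            "descriptives": self.descriptives,
            "importance": self.importance.reset_index(names="feature").to_dict(orient="records"),
        }


def evaluate_folds(folds: Sequence[FoldResult], threshold: float = 0.50) -> pd.DataFrame:
    """Per-outer-fold metric table from out-of-fold predictions."""
    rows = []
    for fr in folds:
        c = confusion(fr.labels, fr.probabilities, threshold)
        row = {"fold": fr.fold, "auc": auc(fr.labels, fr.probabilities)}
        row.update(metrics(c))
        rows.append(row)
    return pd.DataFrame(rows)[["fold", *METRIC_NAMES]]


def aggregate_report(
    folds: Sequence[FoldResult],
    descriptives: dict | None = None,
    threshold: float = 0.50,
) -> EvaluationReport:
    """Mean and sd of each metric across outer folds, plus importances."""
    if len(folds) < 2:
        raise ValueError("aggregation requires at least two folds")
    per_fold = evaluate_folds(folds, threshold)
    summary = pd.DataFrame(
        {
            "mean": per_fold[list(METRIC_NAMES)].mean(),
            "sd": per_fold[list(METRIC_NAMES)].std(ddof=1),
        }
    )
    return EvaluationReport(
        per_fold=per_fold,
        summary=summary,
        descriptives=descriptives or {},
        importance=feature_importance(folds),
    )
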