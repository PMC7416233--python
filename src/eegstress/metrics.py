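"""Confusion-matrix metrics and per-subject report tables.

Standard binary definitions throughout:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

A zero denominator yields 0 with a logged warning rather than NaN, so
degenerate partitions never poison an averaged table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("empty confusion matrix")


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    """2x2 tally of predictions against the designated positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; returning 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The four scores from one confusion matrix."""
    total = c.tp + c.tn + c.fp + c.fn
    return MetricSet(
        accuracy=(c.tp + c.tn) / total,
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1"),
    )


def average_metrics(table: list[MetricSet]) -> MetricSet:
    """Unweighted arithmetic mean of each metric across subjects."""
    if not table:
        raise ValueError("cannot average an empty metric table")
    return MetricSet(
        **{m: float(np.mean([getattr(row, m) for row in table])) for m in METRIC_NAMES}
    )


def metrics_table(per_subject: dict[str, MetricSet], method: str = "proposed") -> pd.DataFrame:
    """Per-subject rows plus an unweighted 'average' row."""
    rows = [
        {"subject": s, "method": method, **ms.as_dict()} for s, ms in per_subject.items()
    ]
    avg = average_metrics(list(per_subject.values()))
    rows.append({"subject": "average", "method": method, **avg.as_dict()})
    return pd.DataFrame(rows)


def roc_curve_points(y_true, scores, positive) -> pd.DataFrame:
    """TPR/FPR sweep over score thresholds (optional report output)."""
    from sklearn.metrics import roc_curve

    y = np.asarray(y_true) == positive
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
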