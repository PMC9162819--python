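"""Confusion-matrix metrics and the train/test split protocol.

The five screening metrics of record — accuracy, specificity, sensitivity,
precision and recall — are computed from raw TP/TN/FP/FN counts.  Sensitivity
and recall share the same formula TP/(TP+FN); both are reported so
comparison tables keep the conventional five rows.  A metric whose
denominator is zero is flagged undefined (NaN) rather than silently set to
zero, so degenerate test sets cannot inflate a comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "compute_metrics",
    "split_holdout",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Five metrics in [0, 1]; NaN marks an undefined (zero-denominator) value."""

    accuracy: float
    precision: float
    recall: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_percent(self) -> dict[str, float]:
        return {k: v * 100.0 for k, v in self.as_dict().items()}


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    values = np.unique(arr)
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1, found values {values.tolist()}")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN for binary labels (positive class = 1)."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_pred has {y_pred.size}"
        )
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, specificity, sensitivity, precision and recall from counts.

    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    specificity = TN / (TN+FP)
    sensitivity = TP / (TP+FN)
    precision   = TP / (TP+FP)
    recall      = TP / (TP+FN)
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    report = MetricReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=prec,
        recall=sens,
        sensitivity=sens,
        specificity=spec,
        undefined=tuple(
            name
            for name, value in (
                ("precision", prec),
                ("recall", sens),
                ("sensitivity", sens),
                ("specificity", spec),
            )
            if math.isnan(value)
        ),
    )
    return report


def split_holdout(
    X, y, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified holdout split; returns (train_idx, test_idx).

    The split is stratified on the binary label so both classes appear on
    each side; too-small inputs raise instead of silently degenerating.
    """
    y = _check_binary(y, "y")
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present before splitting")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=y
    )
    for side, name in ((train_idx, "train"), (test_idx, "test")):
        if len(np.unique(y[side])) < 2:
            raise ValueError(
                f"class missing from the {name} side; use a larger sample"
            )
    return np.sort(train_idx), np.sort(test_idx)
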