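"""Confusion matrix and binary screening performance indexes.

The positive class is Parkinson's disease throughout.  Five indexes are
computed from the TP/FP/TN/FN counts:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    F-score     = 2 TP / (2 TP + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators return 0 with a ``RuntimeWarning`` rather than
raising.  The Matthews coefficient is implemented with the square root in
the denominator (the form that keeps it in [-1, 1]); an uncorrected variant
dividing by the raw product is available via ``corrected=False`` for
auditing against sources that print the formula without the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "f_score",
    "mcc",
    "all_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with PD as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value}")
            object.__setattr__(self, name, int(value))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive=1) -> ConfusionMatrix:
    """Count the four confusion-matrix cells (``positive`` marks PD)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D label vectors")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if labels.size > 2:
        raise ValueError(f"labels must be binary; saw {labels.tolist()}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning 0", RuntimeWarning)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct calls among all evaluated cases."""
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def sensitivity(cm: ConfusionMatrix) -> float:
    """True-positive rate TP / (TP + FN)."""
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """True-negative rate TN / (FP + TN)."""
    return _ratio(cm.tn, cm.fp + cm.tn, "specificity")


def f_score(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall, 2TP / (2TP + FP + FN)."""
    return _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f_score")


def mcc(cm: ConfusionMatrix, corrected: bool = True) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty.

    ``corrected=True`` (default) uses the square-rooted denominator, the
    form bounded in [-1, 1]; ``corrected=False`` divides by the raw product
    of the four marginals instead (audit variant).
    """
    num = cm.tp * cm.tn - cm.fp * cm.fn
    product = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if product == 0:
        warnings.warn("MCC undefined (empty marginal); returning 0", RuntimeWarning)
        return 0.0
    return num / np.sqrt(product) if corrected else num / product


def all_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five indexes as one record (degenerate warnings suppressed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "accuracy": accuracy(cm),
            "sensitivity": sensitivity(cm),
            "specificity": specificity(cm),
            "f_score": f_score(cm),
            "mcc": mcc(cm),
        }
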