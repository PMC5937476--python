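"""Multi-class evaluation metrics over the 6x6 confusion matrix.

All metrics derive from the confusion matrix ``C(i, j)``: the number of
samples of true class ``i`` predicted as class ``j``. Per-class precision
and recall are the usual column- and row-normalized diagonals; macro
precision and recall are their unweighted means over the six classes, and
the macro F1 is the harmonic mean of macro precision and macro recall
(not the mean of per-class F1 scores — the per-class-mean alternative is
available behind a flag for comparison).

A class never predicted has undefined precision (empty column); a class
absent from the truth has undefined recall (empty row). Such values are
reported as 0 and flagged, which full-scale data never triggers but tiny
toy runs can.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .dataset import N_CLASSES

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "precision_per_class",
    "recall_per_class",
    "f1_per_class",
    "macro_metrics",
    "undefined_metric_classes",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Tally the confusion matrix from true and predicted classes in [1, 6]."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 1 or y.max() > N_CLASSES):
            raise ValueError(f"{name} contains classes outside [1, {N_CLASSES}]")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(1, N_CLASSES + 1))
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def precision_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """``C(i,i) / column sum i`` per class; 0 where the column is empty."""
    return _safe_ratio(np.diag(cm.counts), cm.counts.sum(axis=0))


def recall_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """``C(i,i) / row sum i`` per class; 0 where the row is empty."""
    return _safe_ratio(np.diag(cm.counts), cm.counts.sum(axis=1))


def _harmonic(p: np.ndarray | float, r: np.ndarray | float):
    p, r = np.asarray(p, dtype=float), np.asarray(r, dtype=float)
    s = p + r
    return np.where(s > 0, 2 * p * r / np.where(s > 0, s, 1.0), 0.0)


def f1_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Harmonic mean of per-class precision and recall; 0 where undefined."""
    return _harmonic(precision_per_class(cm), recall_per_class(cm))


def macro_metrics(cm: ConfusionMatrix,
                  f1_mode: str = "harmonic_of_macros") -> tuple[float, float, float]:
    """Macro precision, recall and F1.

    Macro precision/recall are unweighted class means. With the default
    ``f1_mode="harmonic_of_macros"`` the macro F1 is the harmonic mean of
    those two aggregates; ``"mean_per_class"`` averages per-class F1
    scores instead.
    """
    p_m = float(precision_per_class(cm).mean())
    r_m = float(recall_per_class(cm).mean())
    if f1_mode == "harmonic_of_macros":
        f1_m = float(_harmonic(p_m, r_m))
    elif f1_mode == "mean_per_class":
        f1_m = float(f1_per_class(cm).mean())
    else:
        raise ValueError(f"unknown f1_mode {f1_mode!r}")
    return p_m, r_m, f1_m


def undefined_metric_classes(cm: ConfusionMatrix) -> dict[str, list[int]]:
    """EC classes (1-based) with undefined precision or recall."""
    return {
        "precision": (np.flatnonzero(cm.counts.sum(axis=0) == 0) + 1).tolist(),
        "recall": (np.flatnonzero(cm.counts.sum(axis=1) == 0) + 1).tolist(),
    }


def metrics_report(cm: ConfusionMatrix) -> dict:
    """All metrics plus undefined-value flags, as a plain dictionary."""
    p_m, r_m, f1_m = macro_metrics(cm)
    return {
        "accuracy": accuracy(cm),
        "precision_per_class": precision_per_class(cm).tolist(),
        "recall_per_class": recall_per_class(cm).tolist(),
        "f1_per_class": f1_per_class(cm).tolist(),
        "macro_precision": p_m,
        "macro_recall": r_m,
        "macro_f1": f1_m,
        "undefined": undefined_metric_classes(cm),
    }
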