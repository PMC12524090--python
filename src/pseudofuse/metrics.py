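"""Evaluation metrics: accuracy, per-class precision/recall/F1, confusion
matrix, and one-vs-rest ROC AUC.

Computation is delegated to scikit-learn; this module fixes the conventions
(macro averaging for summaries, zero-division → 0 with a warning, midrank tie
handling for AUC, a class absent from the truth reported as missing AUC) and
the output schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

__all__ = ["ClassReport", "classification_report", "roc_auc_ovr"]


@dataclass(frozen=True)
class ClassReport:
    """Per-class and summary classification metrics."""

    precision: np.ndarray  # (C,)
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray  # (C,) ints
    accuracy: float
    confusion: np.ndarray  # (C, C) ints, rows = truth

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": [
                {
                    "class": c,
                    "precision": float(self.precision[c]),
                    "recall": float(self.recall[c]),
                    "f1": float(self.f1[c]),
                    "support": int(self.support[c]),
                }
                for c in range(len(self.precision))
            ],
            "confusion": self.confusion.tolist(),
        }


def classification_report(y_true, y_pred, n_classes: int) -> ClassReport:
    """Standard precision/recall/F1 per class plus overall accuracy.

    Zero-division cases (a class never predicted, or absent from truth)
    yield 0 for the affected metric, with a warning.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    labels = np.arange(n_classes)
    if y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes:
        raise ValueError("labels out of range")
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    if (conf.sum(axis=0) == 0).any() or (conf.sum(axis=1) == 0).any():
        warnings.warn("zero-division in precision/recall; reporting 0", RuntimeWarning)
    precision, recall, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    accuracy = float(np.trace(conf) / conf.sum())
    return ClassReport(precision, recall, f1, support, accuracy, conf)


def roc_auc_ovr(y_true, probs: np.ndarray) -> "list[float | None]":
    """One-vs-rest AUC per class via the rank (Mann–Whitney) statistic with
    midrank tie handling; classes absent from the truth get ``None``."""
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or len(y_true) != len(probs):
        raise ValueError("probs must be (n, C) aligned with y_true")
    aucs: list[float | None] = []
    for c in range(probs.shape[1]):
        pos = y_true == c
        if not pos.any() or pos.all():
            aucs.append(None)
        else:
            aucs.append(float(roc_auc_score(pos, probs[:, c])))
    return aucs
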