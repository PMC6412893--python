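"""Confusion matrices and macro-averaged precision/recall/F1.

Per class k, with TP/FP/FN counted from the confusion matrix,
``P_k = TP/(TP+FP)``, ``R_k = TP/(TP+FN)`` and ``F1_k`` their harmonic
mean; the reported P/R/F1 are unweighted (macro) means over classes and
accuracy is the confusion-matrix trace over the total count.  An empty
predicted or truth class yields a 0 metric with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EvalReport", "confusion", "macro_prf", "evaluate"]


@dataclass
class EvalReport:
    """Confusion counts (rows = truth, columns = prediction) and metrics."""

    classes: np.ndarray
    matrix: np.ndarray
    accuracy: float
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    f1_per_class: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def confusion_frame(self, normalize: bool = False) -> pd.DataFrame:
        mat = self.matrix.astype(float)
        if normalize:
            rows = mat.sum(axis=1, keepdims=True)
            mat = np.divide(mat, rows, out=np.zeros_like(mat), where=rows > 0)
        names = [str(c) for c in self.classes]
        return pd.DataFrame(mat, index=names, columns=names)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                str(c): {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                }
                for c, p, r, f in zip(
                    self.classes,
                    self.precision_per_class,
                    self.recall_per_class,
                    self.f1_per_class,
                )
            },
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion(
    y_true: Sequence, y_pred: Sequence, class_order: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Count matrix with rows = truth and columns = prediction.

    Returns ``(classes, matrix)``; ``class_order`` fixes the axis ordering
    (default: sorted union of observed labels).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if class_order is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(class_order)
        seen = set(np.concatenate([y_true, y_pred]).tolist())
        missing = seen - set(classes.tolist())
        if missing:
            raise ValueError(f"labels outside class_order: {sorted(missing)}")
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[index[t], index[p]] += 1
    return classes, mat


def macro_prf(classes: np.ndarray, matrix: np.ndarray) -> EvalReport:
    """Macro-averaged precision/recall/F1 and accuracy from a count matrix."""
    matrix = np.asarray(matrix)
    total = matrix.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(matrix).astype(float)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    if np.any(tp + fp == 0) or np.any(tp + fn == 0):
        warnings.warn(
            "a class has no predicted or no true samples; its metric is set to 0",
            stacklevel=2,
        )
    return EvalReport(
        classes=np.asarray(classes),
        matrix=matrix,
        accuracy=float(tp.sum() / total),
        precision_per_class=precision,
        recall_per_class=recall,
        f1_per_class=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def evaluate(y_true: Sequence, y_pred: Sequence, class_order: Sequence | None = None) -> EvalReport:
    """Convenience wrapper: confusion + macro metrics in one call."""
    classes, mat = confusion(y_true, y_pred, class_order)
    return macro_prf(classes, mat)
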