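"""Confusion matrix and support-weighted classification metrics.

Accuracy is plain multiclass accuracy, trace(cm)/total. Precision, recall
and F1 are computed per class one-vs-rest and averaged with weights equal to
each class's share of the evaluated samples; a class that is never predicted
gets precision 0 (and still counts in the weighted average) rather than a
division error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["confusion_matrix", "weighted_metrics", "EvalReport"]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K×K counts; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError(
            f"label arrays differ in length: {y_true.shape} vs {y_pred.shape}")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValidationError(f"{name} labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class EvalReport:
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    def confusion_to_csv(self, path: str) -> None:
        k = self.confusion.shape[0]
        with open(path, "w") as f:
            f.write("," + ",".join(f"pred_{j}" for j in range(k)) + "\n")
            for i in range(k):
                f.write(f"true_{i}," + ",".join(map(str, self.confusion[i])) + "\n")


def weighted_metrics(cm: np.ndarray) -> EvalReport:
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)     # true counts per class
    predicted = cm.sum(axis=0).astype(float)   # predicted counts per class

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)

    w = support / total
    return EvalReport(
        accuracy=float(tp.sum() / total),
        precision_weighted=float((w * precision).sum()),
        recall_weighted=float((w * recall).sum()),
        f1_weighted=float((w * f1).sum()),
        confusion=cm.astype(int),
    )
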