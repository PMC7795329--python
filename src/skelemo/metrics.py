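"""Evaluation metrics for imbalanced emotion classification.

The headline metric is the unweighted average recall (UAR), the mean of
the per-class recalls, which treats every class equally regardless of
its prevalence.  The weighted average recall (WAR) weights recalls by
class frequency and is numerically equal to overall accuracy.  Both are
derived from the confusion matrix with true classes on the rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "confusion_matrix", "evaluate_predictions", "evaluate"]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     num_classes: int) -> np.ndarray:
    """Integer confusion matrix; rows are true classes, columns predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix with its derived recall metrics."""

    confusion: np.ndarray
    uar: float
    war: float
    per_class_recall: tuple[float, ...]

    @classmethod
    def from_confusion(cls, cm: np.ndarray) -> "EvalReport":
        cm = np.asarray(cm)
        support = cm.sum(axis=1)
        present = support > 0
        if not present.all():
            absent = np.flatnonzero(~present).tolist()
            warnings.warn(
                f"classes {absent} absent from the evaluation set; "
                "UAR averaged over present classes only", stacklevel=2)
        recalls = np.full(cm.shape[0], np.nan)
        recalls[present] = np.diag(cm)[present] / support[present]
        uar = float(np.nanmean(recalls))
        war = float(np.trace(cm) / cm.sum())
        return cls(confusion=cm, uar=uar, war=war,
                   per_class_recall=tuple(recalls.tolist()))

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "uar": self.uar,
            "war": self.war,
            "per_class_recall": list(self.per_class_recall),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_predictions(y_true, y_pred, num_classes: int) -> EvalReport:
    """Build an :class:`EvalReport` from raw label/prediction arrays."""
    return EvalReport.from_confusion(confusion_matrix(y_true, y_pred, num_classes))


def evaluate(model, x: np.ndarray, y_true: np.ndarray) -> EvalReport:
    """Evaluate a classifier with ``predict(x) -> labels`` on a test set."""
    if len(y_true) == 0:
        raise ValueError("evaluation set is empty")
    y_pred = model.predict(x)
    num_classes = getattr(model.cfg, "num_classes", int(max(y_true.max(),
                                                            y_pred.max())) + 1)
    return evaluate_predictions(y_true, y_pred, num_classes)
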