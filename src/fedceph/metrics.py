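"""Multiclass evaluation metrics for one model evaluation.

Accuracy, support-weighted precision/recall/F1, Cohen's kappa, the
unweighted mean of one-vs-rest ROC AUCs, and the 3x3 confusion matrix —
computed from true class indices and per-class scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    auc: float
    confusion: np.ndarray
    n: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    def confusion_csv(self) -> str:
        lines = [",".join(str(v) for v in row) for row in self.confusion]
        return "\n".join(lines) + "\n"


def _safe_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Cohen's kappa with the degenerate chance-agreement case defined.

    When expected agreement p_e is 1 (both marginals concentrated on one
    class), kappa is defined as 1 for perfect agreement and 0 otherwise.
    """
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if len(classes) == 1:
        warnings.warn("kappa degenerate: single class in truth and prediction")
        return 1.0 if np.array_equal(y_true, y_pred) else 0.0
    return float(cohen_kappa_score(y_true, y_pred))


def compute_metrics(
    y_true: np.ndarray, y_score: np.ndarray, n_classes: int = 3
) -> MetricsReport:
    """Evaluate per-class scores against true class indices.

    Predictions are the argmax of ``y_score``.  Precision/recall/F1 use
    support-weighted averaging over the one-vs-rest values; the AUC is the
    unweighted mean of the per-class one-vs-rest ranking AUCs (tied scores
    count one half).  A class absent from ``y_true`` has no defined AUC and
    is excluded from the mean with a warning.
    """
    y_true = np.asarray(y_true, dtype=np.intp)
    y_score = np.asarray(y_score, dtype=np.float64)
    if len(y_true) == 0 or len(y_true) != len(y_score):
        raise ValueError("y_true and y_score must be equal nonzero lengths")
    if not np.all(np.isfinite(y_score)):
        raise ValueError("scores must be finite")
    y_pred = np.argmax(y_score, axis=1)
    labels = list(range(n_classes))
    acc = float(accuracy_score(y_true, y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="weighted", zero_division=0
        )
    kappa = _safe_kappa(y_true, y_pred)
    aucs = []
    for k in labels:
        pos = y_true == k
        if pos.all() or not pos.any():
            warnings.warn(f"class {k} absent from y_true; one-vs-rest AUC undefined")
            continue
        aucs.append(float(roc_auc_score(pos, y_score[:, k])))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    return MetricsReport(
        accuracy=acc,
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        kappa=kappa,
        auc=auc,
        confusion=conf,
        n=len(y_true),
    )
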