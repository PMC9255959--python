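"""Evaluation metrics: balanced accuracy and AUC-ROC."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["balanced_accuracy", "auc_roc"]


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls.

    Insensitive to class imbalance: chance level is 1/#classes regardless of
    class sizes, for binary and multiclass targets alike.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty target vector")
    recalls = []
    for cls in np.unique(y_true):
        m = y_true == cls
        recalls.append(float(np.mean(y_pred[m] == cls)))
    return float(np.mean(recalls))


def auc_roc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve for binary targets, from continuous scores."""
    return float(roc_auc_score(y_true, scores))
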