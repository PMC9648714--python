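"""Scores, thresholding and evaluation metrics for the autoencoder strategies.

The filter score y^F is the total decoded mass (in [0, p]); the inverse score
y^I = 1 - mean squared deviation between input and decoding (in [0, 1]).
Scores are binarised at the threshold that minimises the size-weighted Gini
impurity of the induced split, and assessed with AUC-ROC, AUC-PR and the
Matthews correlation coefficient.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    matthews_corrcoef,
    roc_auc_score,
)

__all__ = [
    "score_filter", "score_inverse", "gini_threshold", "evaluate",
    "EvaluationReport",
]


def score_filter(x_prime: np.ndarray) -> float:
    """Decoded mass: the sum of all cells of the decoding."""
    return float(np.asarray(x_prime, dtype=float).sum())


def score_inverse(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Inverse reconstruction error: 1 - (1/p) * sum (x_ij - x'_ij)^2."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    return float(1.0 - np.mean((x - x_prime) ** 2))


def _weighted_gini(y: np.ndarray, mask_right: np.ndarray) -> float:
    n = len(y)
    gini = 0.0
    for side in (mask_right, ~mask_right):
        m = side.sum()
        if m == 0:
            continue
        p1 = y[side].mean()
        gini += (m / n) * 2.0 * p1 * (1.0 - p1)
    return gini


def gini_threshold(scores: np.ndarray, classes: np.ndarray) -> float:
    """Score cut minimising the size-weighted Gini impurity of the split.

    Candidates are midpoints of consecutive sorted unique scores; ties are
    broken toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes, dtype=int)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("degenerate split: all scores identical")
    best_t, best_g = None, np.inf
    for t in (uniq[:-1] + uniq[1:]) / 2.0:
        g = _weighted_gini(classes, scores >= t)
        if g < best_g - 1e-12:
            best_g, best_t = g, float(t)
    return best_t


@dataclasses.dataclass
class EvaluationReport:
    """AUC-ROC / AUC-PR / MCC plus the confusion counts at the threshold."""

    auc_roc: float
    auc_pr: float
    mcc: float
    threshold: float
    tn: int
    fp: int
    fn: int
    tp: int

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)


def evaluate(
    scores: np.ndarray, classes: np.ndarray, threshold: float
) -> EvaluationReport:
    """Threshold scores and compute AUC-ROC, AUC-PR and MCC.

    A degenerate confusion margin makes the MCC undefined; it is reported as
    0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if len(np.unique(classes)) < 2:
        raise ValueError("both classes must be present")
    predicted = (scores >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(classes, predicted, labels=[0, 1]).ravel()
    margins = [tp + fp, tp + fn, tn + fp, tn + fn]
    if 0 in margins:
        warnings.warn("MCC undefined (zero confusion margin); reporting 0")
        mcc = 0.0
    else:
        mcc = float(matthews_corrcoef(classes, predicted))
    return EvaluationReport(
        auc_roc=float(roc_auc_score(classes, scores)),
        auc_pr=float(average_precision_score(classes, scores)),
        mcc=mcc,
        threshold=float(threshold),
        tn=int(tn), fp=int(fp), fn=int(fn), tp=int(tp),
    )


def scores_frame(
    patient_ids: np.ndarray, scores: np.ndarray, classes: np.ndarray, threshold: float
) -> pd.DataFrame:
    """Tabular per-patient scores for export."""
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "score": scores,
            "class": classes,
            "predicted": (np.asarray(scores) >= threshold).astype(int),
        }
    )
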