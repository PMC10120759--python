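"""Prediction-accuracy metrics: AUC, R^2, Efron's pseudo-R^2, labellers."""

from __future__ import annotations

import logging
import math

import numpy as np
from sklearn.metrics import roc_auc_score

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


def binarize_top_decile(y: np.ndarray) -> np.ndarray:
    """Label the top 10% highest phenotype values as cases.

    The case count is ceil(n/10); ties are broken by stable sort order
    (earlier index wins).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValidationError(f"need at least 10 samples, got {n}")
    n_cases = math.ceil(n / 10)
    order = np.argsort(-y, kind="stable")
    labels = np.zeros(n, dtype=int)
    labels[order[:n_cases]] = 1
    return labels


def binarize_threshold(y: np.ndarray, threshold: float) -> np.ndarray:
    """Label values above a clinical threshold as cases (e.g. BMI 25 kg/m^2,
    LDL 4.1 mmol/L)."""
    return (np.asarray(y, dtype=float) > threshold).astype(int)


def auc(score: np.ndarray, label: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney U / n1*n0, ties count 1/2)."""
    label = np.asarray(label)
    if len(np.unique(label)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(label, np.asarray(score, dtype=float)))


def r2(pred: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of prediction and phenotype."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2 or np.std(y) == 0:
        raise ValidationError("r2 needs n >= 2 and non-constant y")
    if np.std(pred) == 0:
        logger.warning("r2: constant prediction, returning 0")
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


def efron_r2(prob: np.ndarray, y: np.ndarray) -> float:
    """Efron's pseudo-R^2: 1 - sum(y - p)^2 / sum(y - ybar)^2."""
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((prob < 0) | (prob > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    ybar = y.mean()
    denom = float(np.sum((y - ybar) ** 2))
    if denom == 0:
        raise ValidationError("Efron R^2 undefined for single-class y")
    return float(1.0 - np.sum((y - prob) ** 2) / denom)
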