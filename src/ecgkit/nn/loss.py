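"""Weighted cross-entropy for imbalanced multi-class training.

The batch loss is

    L = sum_i w_{y_i} * (-log p_i[y_i]) / sum_i w_{y_i},

i.e. the weighted mean of per-example negative log-likelihoods normalized
by the mean label weight, so uniform weights reduce exactly to the plain
cross-entropy.  Class weights proportional to inverse class frequency
penalize errors on rare beats (S, F) as heavily as on the dominant normal
class.
"""

from __future__ import annotations

import logging

import numpy as np

from .._exceptions import ValidationError
from .layers import softmax

logger = logging.getLogger(__name__)

_EPS = 1e-12


def weighted_cross_entropy(
    probabilities: np.ndarray, labels: np.ndarray, class_weights=None
) -> float:
    """Loss from predicted class probabilities (rows sum to 1)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    if p.ndim != 2 or p.shape[0] != y.size:
        raise ValidationError(
            f"probabilities {p.shape} incompatible with {y.size} labels")
    if class_weights is None:
        w = np.ones(p.shape[1])
    else:
        w = np.asarray(class_weights, dtype=float).ravel()
        if w.size != p.shape[1]:
            raise ValidationError(
                f"{w.size} class weights for {p.shape[1]} classes")
        if np.any(w < 0):
            raise ValidationError("class weights must be nonnegative")
    p_true = p[np.arange(y.size), y]
    if np.any(p_true < _EPS):
        logger.warning(
            "weighted_cross_entropy: %d probabilities below %.0e clamped",
            int(np.sum(p_true < _EPS)), _EPS)
        p_true = np.maximum(p_true, _EPS)
    wy = w[y]
    return float(np.sum(wy * -np.log(p_true)) / np.sum(wy))


def softmax_wce_with_grad(
    logits: np.ndarray, labels: np.ndarray, class_weights=None
) -> tuple[float, np.ndarray]:
    """Fused softmax + weighted cross-entropy; returns (loss, dL/dlogits)."""
    y = np.asarray(labels, dtype=int).ravel()
    p = softmax(np.asarray(logits, dtype=float), axis=1)
    if class_weights is None:
        w = np.ones(p.shape[1])
    else:
        w = np.asarray(class_weights, dtype=float).ravel()
    wy = w[y]
    wsum = float(np.sum(wy))
    p_true = np.maximum(p[np.arange(y.size), y], _EPS)
    loss = float(np.sum(wy * -np.log(p_true)) / wsum)
    grad = p.copy()
    grad[np.arange(y.size), y] -= 1.0
    grad *= (wy / wsum)[:, None]
    return loss, grad
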