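"""Focal loss for imbalanced multiclass training.

    L = mean_i [ -(1 - p_i^t)^gamma * log(p_i^t) ]

p_i^t is the probability the model assigns to the true class of sample i.
gamma = 0 recovers plain cross-entropy; gamma = 3 is the training default —
hard samples (low p^t) keep close-to-full cross-entropy weight while easy
ones are suppressed by the (1 - p^t)^gamma factor. The batch reduction is
the mean (the sum only rescales the learning rate by the batch size).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .errors import ValidationError

__all__ = ["focal_loss", "softmax", "FocalLossParams"]

LOG_CLAMP = 1e-12


class FocalLossParams:
    def __init__(self, gamma: float = 3.0, class_weights=None):
        if gamma < 0:
            raise ValidationError(f"gamma must be >= 0, got {gamma}")
        self.gamma = float(gamma)
        self.class_weights = None if class_weights is None else np.asarray(
            class_weights, dtype=np.float64)


def softmax(logits: Tensor) -> Tensor:
    """Row-wise softmax, max-shifted for stability (the shift is a constant
    in the graph; softmax is invariant to it)."""
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - shift).exp()
    return e * e.sum(axis=1, keepdims=True) ** -1.0


def focal_loss(probs: Tensor | np.ndarray, labels: np.ndarray,
               params: FocalLossParams | None = None, *,
               gamma: float | None = None) -> Tensor:
    """Mean focal loss over a batch of per-sample class-probability vectors.

    probs: (N, K) rows summing to 1 (validated to 1e-5); labels: ints in [0, K).
    """
    if params is None:
        params = FocalLossParams(3.0 if gamma is None else gamma)
    elif gamma is not None:
        raise ValueError("pass gamma via params or keyword, not both")
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    labels = np.asarray(labels)
    n, k = probs.shape
    row_sums = probs.data.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > 1e-5)[0]
    if bad.size:
        raise ValidationError(
            f"probability vector of sample {bad[0]} sums to {row_sums[bad[0]]:.6f}")
    if labels.min() < 0 or labels.max() >= k:
        raise ValidationError(f"labels must lie in [0, {k})")

    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    pt = (probs * Tensor(onehot)).sum(axis=1).clamp_min(LOG_CLAMP)
    log_pt = pt.log()
    if params.gamma == 0.0:
        per_sample = -1.0 * log_pt
    else:
        per_sample = -1.0 * (1.0 - pt) ** params.gamma * log_pt
    if params.class_weights is not None:
        per_sample = per_sample * Tensor(params.class_weights[labels])
    return per_sample.mean()
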