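"""Loss functions returning (scalar loss, gradient w.r.t. the prediction)."""

from __future__ import annotations

import numpy as np

from . import core


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; gradient is 2*(pred-target)/size."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(core._F32) - target.astype(core._F32)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(core._F32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z.astype(np.float64))
    return (e / e.sum(axis=1, keepdims=True)).astype(core._F32)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy for integer labels.

    Returns (loss, dlogits, probs); dlogits = (probs - onehot)/N.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, grad.astype(core._F32), probs
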