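"""Shared loss cores, usable both on plain arrays and on autograd tensors.

Every public loss in the package clamps predicted probabilities to
[CLAMP_EPS, 1 - CLAMP_EPS] before taking logarithms.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

CLAMP_EPS = 1e-7


def _is_tensor(x):
    return isinstance(x, Tensor)


def _clamp(pred):
    if _is_tensor(pred):
        return pred.clip(CLAMP_EPS, 1.0 - CLAMP_EPS)
    return np.clip(np.asarray(pred, dtype=float), CLAMP_EPS, 1.0 - CLAMP_EPS)


def _mean(x):
    return x.mean() if _is_tensor(x) else float(np.mean(x))


def _log(x):
    return x.log() if _is_tensor(x) else np.log(x)


def bce_elements(pred, target):
    """Elementwise binary cross-entropy on clamped probabilities."""
    p = _clamp(pred)
    y = np.asarray(target, dtype=float) if not _is_tensor(target) else target
    return -(y * _log(p) + (1.0 - y) * _log(1.0 - p))


def focal_elements(pred, target, gamma):
    """Elementwise focal terms: (1-p)^g * y * log p + p^g * (1-y) * log(1-p)."""
    if gamma < 0:
        raise ValueError(f"gamma must be nonnegative, got {gamma}")
    p = _clamp(pred)
    y = np.asarray(target, dtype=float) if not _is_tensor(target) else target
    return -((1.0 - p) ** gamma * (y * _log(p))
             + p ** gamma * ((1.0 - y) * _log(1.0 - p)))


def l2_penalty(weights, lam, n):
    """(lam / 2n) * sum of squared weights over all weight arrays."""
    if lam == 0 or not weights:
        return 0.0
    total = None
    for w in weights:
        term = (w * w).sum() if _is_tensor(w) else float(np.sum(np.square(w)))
        total = term if total is None else total + term
    return total * (lam / (2.0 * n))


def mean_loss(elements, penalty=0.0):
    out = _mean(elements)
    if isinstance(penalty, Tensor) or penalty != 0.0:
        out = out + penalty
    return out


def to_float(x):
    return float(x.data) if _is_tensor(x) else float(x)
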