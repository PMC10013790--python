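"""Compound segmentation loss: smoothed Dice loss plus mean binary cross-entropy.

For a batch Ω of images, with p(x) = sigmoid(logit) and binary ground truth
g(x), the per-image loss is

    L_i = [1 - (2 Σ p g + ε) / (Σ p + Σ g + ε)] + (1/|Ω_i|) Σ -[g log p + (1-g) log(1-p)]

and the batch loss is the mean of L_i over the batch. ε (default 1e-5) is a
smoothing constant preventing division by zero on empty masks; logs are
clamped away from 0 and 1 for numerical safety.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import InputError

_LOG_CLAMP = 1e-7


@dataclass
class LossConfig:
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim == 2:
        return a[None]
    if a.ndim == 4 and a.shape[1] == 1:
        return a[:, 0]
    if a.ndim == 3:
        return a
    raise InputError(f"expected (H,W), (N,H,W) or (N,1,H,W) array, got shape {a.shape}")


def _validate(logits: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = _as_batch(logits)
    g = _as_batch(targets)
    if z.shape != g.shape:
        raise InputError(f"logits shape {z.shape} != targets shape {g.shape}")
    vals = np.unique(g)
    if not np.isin(vals, (0, 1)).all():
        raise InputError(f"targets must be binary, found values {vals[:5]}")
    return z, g.astype(z.dtype if z.dtype.kind == "f" else np.float64)


def _terms(z: np.ndarray, g: np.ndarray, eps: float):
    p = expit(z.astype(np.float64))
    pc = np.clip(p, _LOG_CLAMP, 1.0 - _LOG_CLAMP)
    bce = -(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean(axis=(1, 2))
    A = 2.0 * (p * g).sum(axis=(1, 2)) + eps
    B = p.sum(axis=(1, 2)) + g.sum(axis=(1, 2)) + eps
    return p, bce, A, B


def combined_loss(
    logits: np.ndarray, targets: np.ndarray, cfg: LossConfig | None = None
) -> float:
    """Batch-mean Dice + BCE loss; non-negative, minimized at p = g."""
    cfg = cfg or LossConfig()
    z, g = _validate(logits, targets)
    _, bce, A, B = _terms(z, g, cfg.epsilon)
    return float(((1.0 - A / B) + bce).mean())


def combined_loss_grad(
    logits: np.ndarray, targets: np.ndarray, cfg: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the logits.

    Gradient per pixel of image i (batch size N, |Ω_i| pixels):
        [ (p - g)/|Ω_i|  -  (2 g B_i - A_i)/B_i² · p(1-p) ] / N
    """
    cfg = cfg or LossConfig()
    z, g = _validate(logits, targets)
    p, bce, A, B = _terms(z, g, cfg.epsilon)
    n, hw = z.shape[0], z.shape[1] * z.shape[2]
    loss = float(((1.0 - A / B) + bce).mean())
    dice_term = (2.0 * g * B[:, None, None] - A[:, None, None]) / (B**2)[:, None, None]
    grad = ((p - g) / hw - dice_term * p * (1.0 - p)) / n
    return loss, grad.reshape(np.asarray(logits).shape).astype(np.asarray(logits).dtype)
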