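"""Training losses.

Heatmap regression uses pixelwise mean-squared error.  Segmentation uses
cross-entropy plus soft Dice, which is robust to the strong class
imbalance between small foreground structures (e.g. the thin cortical
shell) and the background.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

_EPS = 1e-7


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return diff.square().mean()


def cross_entropy_loss(probs: Tensor, onehot: np.ndarray) -> Tensor:
    # probs: (N, K, H, W) softmax output; onehot same shape
    logp = (probs + _EPS).log()
    n, _, h, w = probs.shape
    return -(Tensor(onehot) * logp).sum() * (1.0 / (n * h * w))


def soft_dice_loss(probs: Tensor, onehot: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - mean soft Dice over classes (batch pooled)."""
    inter = (probs * Tensor(onehot)).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
    dice = (2.0 * inter + smooth) / (denom + smooth)
    k = probs.shape[1]
    return 1.0 - dice.sum() * (1.0 / k)


def ce_dice_loss(probs: Tensor, onehot: np.ndarray) -> Tensor:
    return cross_entropy_loss(probs, onehot) + soft_dice_loss(probs, onehot)
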