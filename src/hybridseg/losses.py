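"""Training objectives: binary cross-entropy, soft Dice, and their sum.

All three accept either plain arrays or autodiff :class:`Tensor` operands
and return Tensors, so the same code serves evaluation (call ``.item()``)
and training (call ``.backward()`` on ``total``). Probabilities are
clamped to [delta, 1-delta] before the logs in BCE; the soft Dice keeps
the stabiliser epsilon in both numerator and denominator so that an
empty-vs-empty comparison scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor

__all__ = ["LossTerms", "bce_loss", "dice_coefficient", "combined_loss",
           "DEFAULT_EPS", "DEFAULT_CLAMP"]

DEFAULT_EPS = 1e-6     # Dice stabiliser
DEFAULT_CLAMP = 1e-7   # BCE probability clamp


@dataclass
class LossTerms:
    """The three terms of the combined objective, as graph tensors."""

    bce: Tensor
    dice: Tensor
    dice_loss: Tensor
    total: Tensor

    def as_floats(self) -> dict[str, float]:
        return {
            "bce": self.bce.item(),
            "dice": self.dice.item(),
            "dice_loss": self.dice_loss.item(),
            "total": self.total.item(),
        }


def _check_pair(p: Tensor, y: Tensor) -> None:
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != label shape {y.shape}")


def bce_loss(p, y, clamp: float = DEFAULT_CLAMP) -> Tensor:
    """Mean binary cross-entropy over all pixels.

    -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
    """
    p, y = astensor(p), astensor(y)
    _check_pair(p, y)
    pc = p.clamp(clamp, 1.0 - clamp)
    ll = y * pc.log() + (1.0 - y) * (1.0 - pc).log()
    return -ll.mean()


def dice_coefficient(p, y, eps: float = DEFAULT_EPS) -> Tensor:
    """Soft Dice: (2 sum(y*p) + eps) / (sum(p) + sum(y) + eps)."""
    if eps < 0:
        raise ValueError("eps must be non-negative")
    p, y = astensor(p), astensor(y)
    _check_pair(p, y)
    inter = (p * y).sum()
    return (2.0 * inter + eps) / (p.sum() + y.sum() + eps)


def combined_loss(p, y, eps: float = DEFAULT_EPS, clamp: float = DEFAULT_CLAMP) -> LossTerms:
    """BCE plus Dice loss (1 - soft Dice); total = bce + dice_loss."""
    p = astensor(p)
    y = astensor(y)
    bce = bce_loss(p, y, clamp)
    dice = dice_coefficient(p, y, eps)
    dice_loss = 1.0 - dice
    return LossTerms(bce=bce, dice=dice, dice_loss=dice_loss, total=bce + dice_loss)
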