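"""Segmentation losses and the deep-supervision schedule.

Five losses over voxel-wise probabilities y_hat in [0,1] against binary
targets y, with soft counts

    Intersection = sum(y_hat * y)         Union = sum(y_hat) + sum(y)
    FP = sum(y_hat * (1 - y))             FN = sum((1 - y_hat) * y)

* Dice loss          1 - 2*Intersection / (Union + eps)
* Tversky loss       1 - Intersection / (Intersection + a*FP + b*FN + eps)
  with a = 0.3, b = 0.7 weighting false positives vs false negatives
* BCE                voxel-mean binary cross-entropy (probabilities clamped)
* Hybrid 1           (1-lam) * Dice + lam * BCE
* Hybrid 2           (1-lam) * Tversky + lam * BCE

The deep-supervision total over the four head losses is
``loss3 + alpha * (loss0 + loss1 + loss2)`` where loss3 belongs to the
full-resolution head; alpha starts at 0.4 and decays by the factor 0.8 once
per configured period.

All functions accept numpy arrays (returning floats) or autograd tensors
(returning tensors), and reduce by summed counts over the whole batch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossConfig", "dice_loss", "tversky_loss", "bce_loss", "hybrid1",
           "hybrid2", "deep_supervision_total", "decay_ds_alpha", "get_loss",
           "LOSS_NAMES"]

_CLAMP = 1e-7


@dataclass
class LossConfig:
    """Loss hyper-parameters with their standard defaults."""

    epsilon: float = 1e-5
    tversky_alpha: float = 0.3
    tversky_beta: float = 0.7
    lam: float = 0.5
    ds_alpha0: float = 0.4
    ds_decay: float = 0.8
    ds_decay_period_epochs: int = 30

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")
        if self.tversky_alpha < 0 or self.tversky_beta < 0 \
                or self.tversky_alpha + self.tversky_beta > 2:
            raise ValueError("invalid Tversky weights")
        if not 0 < self.ds_decay <= 1:
            raise ValueError("deep-supervision decay must lie in (0, 1]")


def _pair(predicted, target):
    p = predicted if isinstance(predicted, Tensor) else Tensor(np.asarray(predicted))
    t = np.asarray(target.data if isinstance(target, Tensor) else target,
                   dtype=np.float32)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs target {t.shape}")
    return p, Tensor(t), not isinstance(predicted, Tensor)


def _ret(value, as_float):
    return value.item() if as_float else value


def dice_loss(predicted, target, epsilon: float = 1e-5):
    """1 - soft Dice: one minus twice the soft intersection over the sum of
    the soft volumes (plus smoothing)."""
    p, t, as_float = _pair(predicted, target)
    inter = (p * t).sum()
    union = p.sum() + t.sum()
    return _ret(1.0 - (2.0 * inter) / (union + epsilon), as_float)


def tversky_loss(predicted, target, alpha: float = 0.3, beta: float = 0.7,
                 epsilon: float = 1e-5):
    """Tversky index loss; alpha weights false positives, beta false
    negatives (alpha = beta = 0.5 recovers Dice)."""
    p, t, as_float = _pair(predicted, target)
    inter = (p * t).sum()
    fp = (p * (1.0 - t)).sum()
    fn = ((1.0 - p) * t).sum()
    return _ret(1.0 - inter / (inter + alpha * fp + beta * fn + epsilon),
                as_float)


def bce_loss(predicted, target):
    """Voxel-mean binary cross-entropy; probabilities clamped to
    [1e-7, 1 - 1e-7] before the logarithms."""
    p, t, as_float = _pair(predicted, target)
    n = float(p.size)
    pc = p.clip(_CLAMP, 1.0 - _CLAMP)
    ll = t * pc.log() + (1.0 - t) * (1.0 - pc).log()
    return _ret(-(ll.sum() / n), as_float)


def hybrid1(predicted, target, lam: float = 0.5, epsilon: float = 1e-5):
    """(1 - lam) * Dice loss + lam * BCE."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * dice_loss(predicted, target, epsilon) \
        + lam * bce_loss(predicted, target)


def hybrid2(predicted, target, lam: float = 0.5, alpha: float = 0.3,
            beta: float = 0.7, epsilon: float = 1e-5):
    """(1 - lam) * Tversky loss + lam * BCE."""
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * tversky_loss(predicted, target, alpha, beta, epsilon) \
        + lam * bce_loss(predicted, target)


def deep_supervision_total(losses, ds_alpha: float):
    """loss3 + ds_alpha * (loss0 + loss1 + loss2).

    ``losses`` holds the four head losses ordered coarsest first; the last
    entry is the full-resolution head."""
    losses = list(losses)
    if len(losses) != 4:
        raise ValueError(f"expected 4 deep-supervision losses, got {len(losses)}")
    aux = losses[0] + losses[1] + losses[2]
    return losses[3] + ds_alpha * aux


def decay_ds_alpha(ds_alpha: float, factor: float = 0.8) -> float:
    """One periodic decay step of the auxiliary-head weight."""
    if ds_alpha < 0:
        raise ValueError("ds_alpha must be non-negative")
    return ds_alpha * factor


def logits_loss(name: str, config: LossConfig | None = None):
    """Like :func:`get_loss` but operating on pre-sigmoid logits, with the
    cross-entropy term evaluated by the fused stable primitive (used in the
    training loop; identical values up to the probability clamp)."""
    from .nn.functional import bce_with_logits

    cfg = config or LossConfig()

    def fn(logits, target):
        if name == "bce":
            return bce_with_logits(logits, target)
        p = logits.sigmoid()
        if name == "dice":
            return dice_loss(p, target, cfg.epsilon)
        if name == "tversky":
            return tversky_loss(p, target, cfg.tversky_alpha,
                                cfg.tversky_beta, cfg.epsilon)
        if name == "hybrid1":
            return (1 - cfg.lam) * dice_loss(p, target, cfg.epsilon) \
                + cfg.lam * bce_with_logits(logits, target)
        if name == "hybrid2":
            return (1 - cfg.lam) * tversky_loss(
                p, target, cfg.tversky_alpha, cfg.tversky_beta, cfg.epsilon) \
                + cfg.lam * bce_with_logits(logits, target)
        raise KeyError(f"unknown loss {name!r}; choose from {LOSS_NAMES}")

    return fn


LOSS_NAMES = ("dice", "tversky", "bce", "hybrid1", "hybrid2")


def get_loss(name: str, config: LossConfig | None = None):
    """Loss function by registry name, closed over the given config."""
    cfg = config or LossConfig()
    table = {
        "dice": lambda p, t: dice_loss(p, t, cfg.epsilon),
        "tversky": lambda p, t: tversky_loss(p, t, cfg.tversky_alpha,
                                             cfg.tversky_beta, cfg.epsilon),
        "bce": bce_loss,
        "hybrid1": lambda p, t: hybrid1(p, t, cfg.lam, cfg.epsilon),
        "hybrid2": lambda p, t: hybrid2(p, t, cfg.lam, cfg.tversky_alpha,
                                        cfg.tversky_beta, cfg.epsilon),
    }
    if name not in table:
        raise KeyError(f"unknown loss {name!r}; choose from {LOSS_NAMES}")
    return table[name]
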