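"""Segmentation loss and evaluation metrics.

The training loss is the sum of a soft Dice loss and the mean binary
cross-entropy between predicted probabilities ``p`` and the binary
reference ``g``:

    L(p, g) = [1 - 2 sum(p g) / (sum(p) + sum(g) + eps)] + BCE(p, g)

with additive smoothing ``eps = 1`` in the Dice denominator so empty
references are well-defined.  Evaluation reports the Dice overlap, sensitivity (recall of
foreground), specificity (recall of background) and the on-target flag
(Dice > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DICE_SMOOTH = 1.0
_CLIP = 1e-7


def dice_loss(p: np.ndarray, g: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    inter = float((p * g).sum())
    return 1.0 - 2.0 * inter / (float(p.sum()) + float(g.sum()) + smooth)


def bce_loss(p: np.ndarray, g: np.ndarray) -> float:
    p = np.clip(np.asarray(p, dtype=np.float64), _CLIP, 1.0 - _CLIP)
    g = np.asarray(g, dtype=np.float64)
    return float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())


def combined_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Soft Dice loss plus mean binary cross-entropy."""
    p = np.asarray(p)
    g = np.asarray(g)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return dice_loss(p, g) + bce_loss(p, g)


def combined_loss_grad_wrt_logits(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gradient of the combined loss with respect to pre-sigmoid logits.

    With ``p = sigmoid(z)`` the cross-entropy term contributes
    ``(p - g)/N`` and the Dice term's gradient w.r.t. ``p`` is chained
    through ``dp/dz = p (1 - p)``.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    n = p.size
    denom = p.sum() + g.sum() + DICE_SMOOTH
    numer = 2.0 * (p * g).sum()
    ddice_dp = -(2.0 * g * denom - numer) / denom**2
    return (p - g) / n + ddice_dp * p * (1.0 - p)


@dataclass
class SegMetrics:
    """Overlap metrics of a predicted mask against the reference."""

    dice: float
    sensitivity: float
    specificity: float
    on_target: bool


def evaluate(pred: np.ndarray, ref: np.ndarray) -> SegMetrics:
    """Dice, sensitivity, specificity and the on-target flag.

    Degenerate conventions: two empty masks have Dice 1 (and sensitivity 1);
    an all-foreground reference has specificity 1.
    """
    p = np.asarray(pred) > 0
    g = np.asarray(ref) > 0
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    tn = int((~p & ~g).sum())
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    sens = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    spec = 1.0 if (tn + fp) == 0 else tn / (tn + fp)
    return SegMetrics(dice=dice, sensitivity=sens, specificity=spec, on_target=dice > 0)
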