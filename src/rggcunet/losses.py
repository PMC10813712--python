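"""Class-wise Dice loss and deep-supervision aggregation.

Plain soft Dice scores only the foreground overlap, so on a lesion-free
patch any prediction — including a sheet of false positives — leaves the
loss at its floor.  The class-wise Dice loss (CDL) fixes this by scoring
the foreground Dice on positive patches (patch label ``y_p = 1``) and the
*background* Dice on negative patches::

    L = 1 - [ y_p * D(p, y) + (1 - y_p) * D(1 - p, 1 - y) ]

with ``D`` the eps-smoothed soft Dice ratio.  A negative patch therefore
pays for every false-positive pixel, and a perfect all-zero mask reaches
loss 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NetworkOutput
from .nn.tensor import Tensor, as_tensor


class ValidationError(ValueError):
    """Inconsistent loss inputs (e.g. patch label contradicts the mask)."""


@dataclass
class LossConfig:
    epsilon: float = 1e-5
    ds_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    main_weight: float = 1.0
    ds_use_cdl: bool = True  # auxiliary heads use CDL (else plain soft Dice)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.main_weight <= 0 or any(w < 0 for w in self.ds_weights):
            raise ValidationError("weights must be non-negative, main positive")


def soft_dice(pred, target, epsilon: float = 1e-5) -> Tensor:
    """Eps-smoothed soft Dice ``(2*sum(p*y) + eps) / (sum(p) + sum(y) + eps)``.

    1-D (N pixels) and 2-D (H, W) inputs are a single sample and give a
    scalar tensor; 3-D inputs are a batch (N, H, W) and give a per-sample
    vector.  Identical shapes are required.
    """
    pred, target = as_tensor(pred), as_tensor(target)
    if pred.shape != target.shape:
        raise ValidationError(
            f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    axes = tuple(range(1, pred.ndim)) if pred.ndim >= 3 else None
    inter = (pred * target).sum(axis=axes)
    denom = pred.sum(axis=axes) + target.sum(axis=axes) + epsilon
    return (2.0 * inter + epsilon) / denom


def patch_labels(target) -> np.ndarray:
    """Per-sample patch label: 1 iff the mask has any foreground pixel."""
    td = as_tensor(target).data
    if td.ndim <= 2:
        return np.asarray(float(td.any()))
    return td.reshape(td.shape[0], -1).any(axis=1).astype(td.dtype)


def class_wise_dice_loss(pred, target, y_p=None, epsilon: float = 1e-5) -> Tensor:
    """CDL of a foreground-probability map against a binary mask.

    ``pred``/``target``: (H, W) or (N, H, W).  ``y_p`` (scalar or length-N)
    defaults to the label derived from ``target``; if given it must agree
    with the mask content.
    """
    pred, target = as_tensor(pred), as_tensor(target)
    derived = patch_labels(target)
    if y_p is None:
        y_p = derived
    else:
        y_p = np.asarray(y_p, dtype=float)
        if not np.array_equal(y_p.astype(bool), derived.astype(bool)):
            raise ValidationError(
                "patch label y_p contradicts the mask content")
    d_fg = soft_dice(pred, target, epsilon)
    d_bg = soft_dice(1.0 - pred, 1.0 - target, epsilon)
    loss = 1.0 - (Tensor(y_p) * d_fg + Tensor(1.0 - y_p) * d_bg)
    return loss.mean() if loss.ndim else loss


def total_loss(output: NetworkOutput, target, y_p=None,
               cfg: LossConfig | None = None) -> Tensor:
    """Weighted CDL over the main head and the four deep-supervision heads,
    normalised by the total weight.

    ``output.main`` / ``output.aux[k]`` are (N, 2, H, W) probability maps;
    channel 1 is the foreground.  Training-mode outputs must carry the four
    auxiliary maps whenever any deep-supervision weight is non-zero.
    """
    cfg = cfg or LossConfig()

    def head_loss(prob_map, use_cdl=True):
        fg = prob_map[:, 1]
        if use_cdl:
            return class_wise_dice_loss(fg, target, y_p, cfg.epsilon)
        d = soft_dice(fg, as_tensor(target), cfg.epsilon)
        return (1.0 - d).mean() if d.ndim else 1.0 - d

    loss = cfg.main_weight * head_loss(output.main)
    weight_sum = cfg.main_weight
    if any(w > 0 for w in cfg.ds_weights):
        if len(output.aux) != len(cfg.ds_weights):
            raise ValidationError(
                f"expected {len(cfg.ds_weights)} auxiliary maps in training "
                f"mode, got {len(output.aux)}")
        for w, aux in zip(cfg.ds_weights, output.aux):
            if w > 0:
                loss = loss + w * head_loss(aux, use_cdl=cfg.ds_use_cdl)
                weight_sum += w
    return loss * (1.0 / weight_sum)
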