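"""Training losses: annotator-robust edge supervision and BCE+Dice body loss.

Edge maps are dominated by negatives and their ground truth is noisy
near the boundary, so the edge branch uses a class-balanced log loss
with an ignore band: a pixel with ground-truth confidence y is

    positive   (y ≥ γ):      −β · log p
    negative   (y = 0):      −α · log(1 − p),   α = λ·(1 − β)
    ambiguous  (0 < y < γ):  ignored,

with defaults γ = 0.6, β = 0.8 (the negative-sample proportion) and
λ = 2.0, summed over pixels and over the four deeply supervised stage
maps.  The body branch combines mean binary cross-entropy and
ε-smoothed soft Dice, L_body = λ1·L_bce + λ2·L_dice with λ1 = 0.6,
λ2 = 0.4, and the total is L = L_body + ω·L_edge with ω = 0.3.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["LossWeights", "LossReport", "edge_pixel_loss", "edge_loss_total",
           "bce_loss", "dice_loss", "body_loss", "total_loss"]

_CLAMP_EPS = 1e-7
_DICE_EPS = 1.0


@dataclasses.dataclass
class LossWeights:
    gamma: float = 0.6       # positive-confidence threshold
    beta: float = 0.8        # negative-sample proportion
    lam: float = 2.0         # balance hyperparameter; α = λ·(1−β)
    lambda1: float = 0.6     # BCE weight in the body loss
    lambda2: float = 0.4     # Dice weight in the body loss
    omega: float = 0.3       # edge/body balance in the total loss
    edge_reduction: str = "sum"   # sum over pixels; "mean" togglable
    bce_reduction: str = "mean"

    @property
    def alpha(self) -> float:
        return self.lam * (1.0 - self.beta)

    def validate(self):
        if not (0 < self.gamma < 1):
            raise ValueError(f"gamma {self.gamma} outside (0,1)")
        if not (0 < self.beta < 1):
            raise ValueError(f"beta {self.beta} outside (0,1)")
        if self.edge_reduction not in ("sum", "mean") or \
           self.bce_reduction not in ("sum", "mean"):
            raise ValueError("reductions must be 'sum' or 'mean'")


@dataclasses.dataclass
class LossReport:
    edge: float
    bce: float
    dice: float
    body: float
    total: float
    per_stage_edge: list

    def __post_init__(self):
        w = self._weights
        assert abs(self.body - (w.lambda1 * self.bce + w.lambda2 * self.dice)) < 1e-4 * (1 + abs(self.body))
        assert abs(self.total - (self.body + w.omega * self.edge)) < 1e-4 * (1 + abs(self.total))

    _weights: LossWeights = dataclasses.field(default_factory=LossWeights)


def _clamped(pred: Tensor) -> Tensor:
    lo, hi = _CLAMP_EPS, 1.0 - _CLAMP_EPS
    data = np.clip(pred.data, lo, hi)
    mask = (pred.data > lo) & (pred.data < hi)

    out = Tensor(data, requires_grad=pred.requires_grad,
                 _parents=(pred,) if pred.requires_grad else ())
    if out.requires_grad:
        out._backward = lambda g: pred._accum(g * mask)
    return out


def edge_pixel_loss(pred: Tensor, gt, w: LossWeights | None = None) -> Tensor:
    """Annotator-robust edge loss, reduced per ``w.edge_reduction``.

    ``gt`` holds per-pixel edge confidences in [0, 1]; binary masks are
    the common case (confidence ∈ {0, 1}).
    """
    w = w or LossWeights()
    w.validate()
    pred = ad.tensor(pred)
    gt = np.asarray(gt, dtype=np.float32)
    if gt.min() < 0 or gt.max() > 1:
        raise ValueError("edge ground truth must lie in [0, 1]")
    p = _clamped(pred)
    pos = gt >= w.gamma
    neg = gt == 0
    pos_term = ad.log(p) * Tensor(pos.astype(np.float32))
    neg_term = ad.log(1.0 - p) * Tensor(neg.astype(np.float32))
    loss = -(w.beta * pos_term + w.alpha * neg_term)
    return loss.mean() if w.edge_reduction == "mean" else loss.sum()


def edge_loss_total(edge_maps: list, gt_edge, w: LossWeights | None = None):
    """Deep supervision: sum of the per-stage edge losses.

    Returns (total, [per-stage scalars]).
    """
    w = w or LossWeights()
    gt = np.asarray(gt_edge, dtype=np.float32)
    per_stage = []
    for m in edge_maps:
        if m.shape[-2:] != gt.shape[-2:]:
            raise ValueError(
                f"edge map {m.shape[-2:]} does not match ground truth {gt.shape[-2:]}")
        per_stage.append(edge_pixel_loss(m, gt.reshape(m.shape), w))
    total = per_stage[0]
    for t in per_stage[1:]:
        total = total + t
    return total, per_stage


def bce_loss(pred: Tensor, gt, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy −[ŷ·log y + (1−ŷ)·log(1−y)], mean over pixels."""
    pred = ad.tensor(pred)
    gt = np.asarray(gt, dtype=np.float32).reshape(pred.shape)
    p = _clamped(pred)
    ll = ad.log(p) * Tensor(gt) + ad.log(1.0 - p) * Tensor(1.0 - gt)
    return -(ll.mean() if reduction == "mean" else ll.sum())


def dice_loss(pred: Tensor, gt, eps: float = _DICE_EPS) -> Tensor:
    """Soft Dice loss 1 − (2Σyŷ + ε)/(Σy + Σŷ + ε); 0 for matching
    empty masks by the ε-smoothing convention."""
    pred = ad.tensor(pred)
    gt = np.asarray(gt, dtype=np.float32).reshape(pred.shape)
    inter = (pred * Tensor(gt)).sum()
    denom = pred.sum() + float(gt.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def body_loss(pred: Tensor, gt, w: LossWeights | None = None) -> tuple:
    """λ1·BCE + λ2·Dice; returns (body, bce, dice) scalars."""
    w = w or LossWeights()
    b = bce_loss(pred, gt, reduction=w.bce_reduction)
    d = dice_loss(pred, gt)
    return w.lambda1 * b + w.lambda2 * d, b, d


def total_loss(body_pred: Tensor, body_gt, edge_maps: list, edge_gt,
               w: LossWeights | None = None) -> tuple:
    """Full objective L = L_body + ω·L_edge.

    Returns (loss tensor for backprop, LossReport of detached scalars).
    """
    w = w or LossWeights()
    w.validate()
    l_body, l_bce, l_dice = body_loss(body_pred, body_gt, w)
    l_edge, per_stage = edge_loss_total(edge_maps, edge_gt, w)
    loss = l_body + w.omega * l_edge
    report = LossReport(edge=l_edge.item(), bce=l_bce.item(), dice=l_dice.item(),
                        body=l_body.item(), total=loss.item(),
                        per_stage_edge=[t.item() for t in per_stage], _weights=w)
    return loss, report
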