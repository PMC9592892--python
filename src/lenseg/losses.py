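"""Pixel-wise training losses.

The network is supervised per pixel with softmax cross-entropy.  Two
readings of the loss are provided:

``literal_eq1``
    Cross-entropy between ``softmax(q)`` and ``softmax(p)`` — the ground
    truth is itself passed through a channel softmax before entering the
    cross-entropy.  With a one-hot ground truth this has a strictly
    positive floor: for K classes the minimum is the entropy of
    ``(e, 1, ..., 1)/(e + K - 1)`` (~0.9754 for K = 3), reached when the
    prediction's softmax equals the target's.

``hard_onehot``
    The conventional reading: ``-log softmax(p)[true class]``, which tends
    to zero as the true-class logit grows.  This is the form that actually
    drives the prediction to the labels and is the practical training
    default.

Auxiliary decoder heads are supervised at their own resolution against the
ground truth bilinearly downsampled (``downsample_gt``), and the total loss
is ``main + sum_t mu_t * aux_t`` with the auxiliary weights mu = (0.2, 0.3)
increasing with decoder depth.  A soft-Jaccard IoU loss is available as the
ablation alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import functional as F
from .nn.autograd import Tensor, as_tensor

MODES = ("literal_eq1", "hard_onehot", "iou_loss")

__all__ = [
    "LossConfig",
    "PredictionTarget",
    "pixel_ce",
    "downsample_gt",
    "total_loss",
    "iou_loss",
    "one_hot",
    "literal_loss_floor",
]


@dataclass(frozen=True)
class LossConfig:
    mode: str = "literal_eq1"
    aux_weights: tuple[float, ...] = (0.2, 0.3)
    num_classes: int = 3

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown loss mode {self.mode!r}; pick from {MODES}")
        if any(not 0.0 < w <= 1.0 for w in self.aux_weights):
            raise ValueError("auxiliary weights must lie in (0, 1]")
        if any(a > b for a, b in zip(self.aux_weights, self.aux_weights[1:])):
            raise ValueError("auxiliary weights must be non-decreasing with depth")


@dataclass
class PredictionTarget:
    """Paired logits ``p`` and target field ``q``, both (K, H, W) or (N, K, H, W)."""

    p: np.ndarray | Tensor
    q: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=np.float64)
        p_shape = self.p.shape
        if p_shape != self.q.shape:
            raise ValueError(f"p/q shape mismatch: {p_shape} vs {self.q.shape}")
        if np.any(self.q < 0) or np.any(self.q > 1):
            raise ValueError("target entries must lie in [0, 1]")


def _channel_axis(shape) -> int:
    if len(shape) == 3:
        return 0
    if len(shape) == 4:
        return 1
    raise ValueError(f"expected (K,H,W) or (N,K,H,W), got shape {shape}")


def one_hot(classes: np.ndarray, num_classes: int) -> np.ndarray:
    """(H, W) integer labels -> (K, H, W) one-hot float field."""
    classes = np.asarray(classes)
    out = np.zeros((num_classes,) + classes.shape)
    for k in range(num_classes):
        out[k] = classes == k
    return out


def _softmax_np(z, axis):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _hard_target(q: np.ndarray, axis: int) -> np.ndarray:
    """Collapse a (possibly soft) target field to one-hot along ``axis``."""
    idx = np.argmax(q, axis=axis)
    hard = np.zeros_like(q)
    np.put_along_axis(hard, np.expand_dims(idx, axis), 1.0, axis=axis)
    return hard


def pixel_ce(pt: PredictionTarget, mode: str = "literal_eq1") -> Tensor:
    """Mean per-pixel cross-entropy; differentiable in the logits.

    Returns a scalar :class:`Tensor`; call ``.item()`` for the float value.
    """
    p = as_tensor(pt.p)
    axis = _channel_axis(p.shape)
    if mode == "literal_eq1":
        target = _softmax_np(pt.q, axis)
    elif mode == "hard_onehot":
        target = _hard_target(pt.q, axis)
    else:
        raise ValueError(f"pixel_ce mode must be literal_eq1 or hard_onehot, got {mode!r}")
    return F.softmax_cross_entropy(p, target, channel_axis=axis)


def downsample_gt(q: np.ndarray, target_h: int, target_w: int, mode: str = "literal_eq1") -> np.ndarray:
    """Bilinearly downsample a one-hot (K, H, W) target to (K, th, tw).

    Bilinear weights sum to one, so the channel-sum stays exactly 1 per
    pixel (soft labels at class boundaries).  In ``hard_onehot`` mode the
    per-pixel argmax of the soft field is re-one-hot-encoded instead.
    """
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 3:
        raise ValueError(f"expected (K, H, W) target, got shape {q.shape}")
    _, h, w = q.shape
    if target_h < 1 or target_w < 1:
        raise ValueError("target dims must be positive")
    if target_h > h or target_w > w:
        raise ValueError("downsample_gt only reduces resolution")
    ah = F._interp_matrix(target_h, h)
    aw = F._interp_matrix(target_w, w)
    soft = np.einsum("oh,khw,pw->kop", ah, q, aw)
    if mode == "hard_onehot":
        return _hard_target(soft, 0)
    return soft


def total_loss(main, aux, cfg: LossConfig):
    """Weighted deep-supervision total: ``1.0 * main + sum_t mu_t * aux_t``."""
    aux = list(aux)
    if len(aux) != len(cfg.aux_weights):
        raise ValueError(
            f"{len(aux)} auxiliary losses but {len(cfg.aux_weights)} weights"
        )
    if isinstance(main, Tensor) or any(isinstance(a, Tensor) for a in aux):
        return F.weighted_sum([as_tensor(main), *map(as_tensor, aux)], [1.0, *cfg.aux_weights])
    return float(main) + sum(w * a for w, a in zip(cfg.aux_weights, aux))


def iou_loss(pt: PredictionTarget) -> Tensor:
    """1 - mean over classes of soft-Jaccard(softmax(p), q)."""
    p = as_tensor(pt.p)
    axis = _channel_axis(p.shape)
    if p.data.size == 0:
        raise ValueError("empty image")
    return F.soft_iou_loss(p, pt.q, channel_axis=axis)


def literal_loss_floor(num_classes: int) -> float:
    """Minimum of the literal loss for a one-hot target.

    The target softmax is ``(e, 1, ..., 1)/(e + K - 1)``; the loss floor is
    that distribution's entropy, reached when softmax(p) matches it.
    """
    e = np.e
    z = np.array([e] + [1.0] * (num_classes - 1))
    sm = z / z.sum()
    return float(-(sm * np.log(sm)).sum())
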