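"""Box algebra: IoU, shape-aware IoU regression loss terms, and NMS.

Pure math substrate shared by the detection head and the loss module.
Scalar entry points operate on :class:`Box`; a batched differentiable
variant (:func:`shape_iou_loss_t`) operates on ``(N, 4)`` autograd
tensors in ``xyxy`` layout for training.

Conventions: continuous pixel coordinates, origin top-left, ``xyxy``
internal layout, area ``(x2 - x1) * (y2 - y1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "Box",
    "Detection",
    "ShapeIoUTerms",
    "iou",
    "iou_matrix",
    "shape_weights",
    "shape_iou_terms",
    "shape_iou_loss",
    "shape_iou_loss_t",
    "nms",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in continuous pixel coordinates (xyxy)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"invalid box: ({self.x1},{self.y1},{self.x2},{self.y2})")

    @property
    def w(self) -> float:
        return self.x2 - self.x1

    @property
    def h(self) -> float:
        return self.y2 - self.y1

    @property
    def xc(self) -> float:
        return 0.5 * (self.x1 + self.x2)

    @property
    def yc(self) -> float:
        return 0.5 * (self.y1 + self.y2)

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.xc, self.yc, self.w, self.h)

    @classmethod
    def from_xywh(cls, xc: float, yc: float, w: float, h: float) -> "Box":
        return cls(xc - w / 2, yc - h / 2, xc + w / 2, yc + h / 2)

    def to_xyxy(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    def clip(self, width: float, height: float) -> "Box":
        return Box(
            min(max(self.x1, 0.0), width),
            min(max(self.y1, 0.0), height),
            min(max(self.x2, 0.0), width),
            min(max(self.y2, 0.0), height),
        )


@dataclass(frozen=True)
class Detection:
    box: Box
    score: float
    class_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0,1], got {self.score}")


@dataclass
class ShapeIoUTerms:
    """Intermediate quantities of the shape-aware IoU loss."""

    iou: float
    ww: float
    hh: float
    c2: float  # squared diagonal of the smallest enclosing box
    distance_shape: float
    omega_w: float
    omega_h: float
    omega_shape: float
    scale: float = 1.0
    theta: float = 4.0


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 for a degenerate union."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = a.area + b.area - inter
    if union <= 0.0:
        warnings.warn("degenerate zero-area union in iou(); returning 0", stacklevel=2)
        return 0.0
    return inter / union


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (Na,4) / (Nb,4) xyxy arrays -> (Na, Nb)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, _EPS), 0.0)


def shape_weights(gt: Box, scale: float) -> tuple[float, float]:
    """Directional weight pair (ww, hh) from the ground-truth box shape.

    ``ww = 2 * w^s / (w^s + h^s)`` and ``hh = 2 * h^s / (w^s + h^s)``;
    the pair always sums to 2.
    """
    if gt.w <= 0 or gt.h <= 0:
        raise ValueError("ground-truth box must have positive width and height")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    ws = gt.w**scale
    hs = gt.h**scale
    denom = ws + hs
    return (2.0 * ws / denom, 2.0 * hs / denom)


def shape_iou_terms(pred: Box, gt: Box, scale: float = 1.0, theta: float = 4.0) -> ShapeIoUTerms:
    """All intermediate terms of the shape-aware IoU loss for one pair."""
    ww, hh = shape_weights(gt, scale)
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    c2 = cw * cw + ch * ch
    dx2 = (pred.xc - gt.xc) ** 2
    dy2 = (pred.yc - gt.yc) ** 2
    distance = (hh * dx2 + ww * dy2) / max(c2, _EPS)
    omega_w = hh * abs(pred.w - gt.w) / max(pred.w, gt.w, _EPS)
    omega_h = ww * abs(pred.h - gt.h) / max(pred.h, gt.h, _EPS)
    omega = (1.0 - np.exp(-omega_w)) ** theta + (1.0 - np.exp(-omega_h)) ** theta
    return ShapeIoUTerms(
        iou=iou(pred, gt),
        ww=ww,
        hh=hh,
        c2=c2,
        distance_shape=distance,
        omega_w=omega_w,
        omega_h=omega_h,
        omega_shape=omega,
        scale=scale,
        theta=theta,
    )


def shape_iou_loss(pred: Box, gt: Box, scale: float = 1.0, theta: float = 4.0) -> float:
    """``1 - IoU + distance_shape + 0.5 * Omega_shape`` for one box pair."""
    t = shape_iou_terms(pred, gt, scale=scale, theta=theta)
    return (1.0 - t.iou) + t.distance_shape + 0.5 * t.omega_shape


def shape_iou_loss_t(
    pred: Tensor, gt: np.ndarray, scale: float = 1.0, theta: float = 4.0
) -> Tensor:
    """Differentiable batched shape-aware IoU loss.

    pred: (N,4) autograd tensor, xyxy; gt: (N,4) array. Returns the mean
    loss over the N pairs.
    """
    gt = np.asarray(gt, dtype=np.float32)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    gw = gx2 - gx1
    gh = gy2 - gy1
    ws = gw**scale
    hs = gh**scale
    ww = 2.0 * ws / (ws + hs)
    hh = 2.0 * hs / (ws + hs)

    ix = nn.minimum(px2, gx2) - nn.maximum(px1, gx1)
    iy = nn.minimum(py2, gy2) - nn.maximum(py1, gy1)
    inter = nn.maximum(ix, 0.0) * nn.maximum(iy, 0.0)
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + Tensor(area_g) - inter
    iou_t = inter / (union + _EPS)

    cw = nn.maximum(px2, gx2) - nn.minimum(px1, gx1)
    ch = nn.maximum(py2, gy2) - nn.minimum(py1, gy1)
    c2 = cw * cw + ch * ch + _EPS

    pxc = (px1 + px2) * 0.5
    pyc = (py1 + py2) * 0.5
    gxc = (gx1 + gx2) * 0.5
    gyc = (gy1 + gy2) * 0.5
    distance = (Tensor(hh) * (pxc - Tensor(gxc)) ** 2 + Tensor(ww) * (pyc - Tensor(gyc)) ** 2) / c2

    pw = px2 - px1
    ph = py2 - py1
    dw = pw - Tensor(gw)
    dh = ph - Tensor(gh)
    abs_dw = nn.maximum(dw, -dw)
    abs_dh = nn.maximum(dh, -dh)
    omega_w = Tensor(hh) * abs_dw / nn.maximum(nn.maximum(pw, Tensor(gw)), _EPS)
    omega_h = Tensor(ww) * abs_dh / nn.maximum(nn.maximum(ph, Tensor(gh)), _EPS)
    omega = (1.0 - (-omega_w).exp()) ** theta + (1.0 - (-omega_h).exp()) ** theta

    loss = (1.0 - iou_t) + distance + 0.5 * omega
    return loss.mean()


def nms(
    dets: list[Detection], iou_thr: float = 0.5, score_thr: float = 0.0
) -> list[Detection]:
    """Greedy highest-score-first non-maximum suppression, per class.

    Ties on score are broken by input order (stable).  Survivors are
    returned sorted by descending score.
    """
    if not (0.0 <= iou_thr <= 1.0 and 0.0 <= score_thr <= 1.0):
        raise ValueError("thresholds must be in [0,1]")
    cand = [(i, d) for i, d in enumerate(dets) if d.score >= score_thr]
    cand.sort(key=lambda t: (-t[1].score, t[0]))
    keep: list[Detection] = []
    for _, d in cand:
        if all(
            k.class_id != d.class_id or iou(k.box, d.box) <= iou_thr for k in keep
        ):
            keep.append(d)
    return keep
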