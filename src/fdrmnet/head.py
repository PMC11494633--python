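"""Detection heads and target assignment.

LPSDH (lightweight parameter-shared detection head): one pointwise "dot"
convolution plus a stack of 3x3 convolutions whose weights are literally
shared across the three pyramid levels, while every level keeps its own
batch-normalization parameters and statistics.  Per-level pointwise output
layers emit class probabilities, 4 box-regression values, and a confidence
map per location (anchor-free, one prediction per cell).

The ablation variant (``IndependentHeads``) builds three decoupled heads
per level (separate classification and regression branches) of the same
widths with no weight sharing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .geometry import Box, Detection, nms
from .nn import BatchNorm2d, Conv2d, Module, Sequential, SiLU, Tensor

__all__ = [
    "HeadOutputs",
    "LPSDH",
    "IndependentHeads",
    "decode",
    "encode_box",
    "decode_box",
    "assign_targets",
    "Assignment",
]

# nominal object side = SIZE_GAIN * stride for a cell of that level
SIZE_GAIN = 4.0


@dataclass
class HeadOutputs:
    """Per-level activated maps: class probs (nc,H,W), raw box regression
    (4,H,W), confidence (1,H,W); plus the level strides."""

    cls: list[Tensor]
    box: list[Tensor]
    conf: list[Tensor]
    strides: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.cls) == len(self.box) == len(self.conf) == len(self.strides)):
            raise ValueError("per-level output lists must align")


class _SharedStack(Module):
    """The shared conv parameters: one dot conv + ``depth`` 3x3 convs."""

    def __init__(self, cin: int, width: int, depth: int):
        super().__init__()
        self.dot = Conv2d(cin, width, 1, bias=False)
        self.convs = Sequential(*[Conv2d(width, width, 3, bias=False) for _ in range(depth)])
        self.depth = depth


class _LevelOutputs(Module):
    def __init__(self, width: int, nc: int):
        super().__init__()
        self.cls_out = Conv2d(width, nc, 1, bias=True)
        self.box_out = Conv2d(width, 4, 1, bias=True)
        self.conf_out = Conv2d(width, 1, 1, bias=True)


class LPSDH(Module):
    """Parameter-shared head over (P3, P4, P5)."""

    def __init__(self, cin: int, width: int = 128, depth: int = 2, nc: int = 1,
                 strides: tuple[int, ...] = (8, 16, 32)):
        super().__init__()
        self.nc = nc
        self.strides = strides
        self.shared = _SharedStack(cin, width, depth)
        self.act = SiLU()
        # independent per-level batch norms: (depth+1) per level
        self.bns = Sequential(
            *[Sequential(*[BatchNorm2d(width) for _ in range(depth + 1)]) for _ in strides]
        )
        self.outs = Sequential(*[_LevelOutputs(width, nc) for _ in strides])
        self.cin = cin

    def forward(self, *levels: Tensor) -> HeadOutputs:
        if len(levels) != len(self.strides):
            raise ValueError("head expects one feature map per stride")
        for f in levels:
            if f.shape[1] != self.cin:
                raise ValueError(
                    f"shared head requires equal level widths {self.cin}, got {f.shape[1]}"
                )
        cls, box, conf = [], [], []
        for li, x in enumerate(levels):
            bns = self.bns[li]
            x = self.act(bns[0](self.shared.dot(x)))
            for j, cv in enumerate(self.shared.convs):
                x = self.act(bns[j + 1](cv(x)))
            out = self.outs[li]
            cls.append(out.cls_out(x).sigmoid())
            box.append(out.box_out(x))
            conf.append(out.conf_out(x).sigmoid())
        return HeadOutputs(cls=cls, box=box, conf=conf, strides=self.strides)


class _DecoupledLevelHead(Module):
    """One level of the unshared ablation head: separate classification and
    regression branches, each with its own dot conv + 3x3 stack."""

    def __init__(self, cin: int, width: int, depth: int, nc: int):
        super().__init__()
        def branch():
            mods: list[Module] = [Conv2d(cin, width, 1, bias=False), BatchNorm2d(width), SiLU()]
            for _ in range(depth):
                mods += [Conv2d(width, width, 3, bias=False), BatchNorm2d(width), SiLU()]
            return Sequential(*mods)

        self.cls_branch = branch()
        self.reg_branch = branch()
        self.cls_out = Conv2d(width, nc, 1, bias=True)
        self.box_out = Conv2d(width, 4, 1, bias=True)
        self.conf_out = Conv2d(width, 1, 1, bias=True)

    def forward(self, x: Tensor):
        c = self.cls_branch(x)
        r = self.reg_branch(x)
        return self.cls_out(c).sigmoid(), self.box_out(r), self.conf_out(r).sigmoid()


class IndependentHeads(Module):
    """Three decoupled per-level heads of the same widths (no sharing)."""

    def __init__(self, cin: int, width: int = 128, depth: int = 2, nc: int = 1,
                 strides: tuple[int, ...] = (8, 16, 32)):
        super().__init__()
        self.nc = nc
        self.strides = strides
        self.cin = cin
        self.heads = Sequential(*[_DecoupledLevelHead(cin, width, depth, nc) for _ in strides])

    def forward(self, *levels: Tensor) -> HeadOutputs:
        cls, box, conf = [], [], []
        for head, x in zip(self.heads, levels):
            c, b, o = head(x)
            cls.append(c)
            box.append(b)
            conf.append(o)
        return HeadOutputs(cls=cls, box=box, conf=conf, strides=self.strides)


# -- box encoding ------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def decode_box(t: np.ndarray, gy: int, gx: int, stride: float) -> Box:
    """Map raw regression values (tx, ty, tw, th) at cell (gy, gx) to an
    image-space box: centre = (cell + sigmoid(offset)) * stride, size =
    SIZE_GAIN * stride * exp(t)."""
    tx, ty, tw, th = (float(v) for v in t)
    cx = (gx + _sigmoid(tx)) * stride
    cy = (gy + _sigmoid(ty)) * stride
    w = SIZE_GAIN * stride * np.exp(np.clip(tw, -8, 8))
    h = SIZE_GAIN * stride * np.exp(np.clip(th, -8, 8))
    return Box.from_xywh(cx, cy, w, h)


def encode_box(box: Box, gy: int, gx: int, stride: float) -> np.ndarray:
    """Inverse of :func:`decode_box` (for target construction and tests)."""
    tx = _logit(box.xc / stride - gx)
    ty = _logit(box.yc / stride - gy)
    tw = np.log(max(box.w, 1e-6) / (SIZE_GAIN * stride))
    th = np.log(max(box.h, 1e-6) / (SIZE_GAIN * stride))
    return np.array([tx, ty, tw, th], dtype=np.float64)


def decode(
    outputs: HeadOutputs,
    conf_thr: float = 0.25,
    iou_thr: float = 0.5,
    image_size: tuple[int, int] | None = None,
) -> list[Detection]:
    """Turn head maps into final detections: score = confidence x class
    probability, threshold, per-class NMS, clip to image bounds."""
    dets: list[Detection] = []
    for cls_m, box_m, conf_m, s in zip(outputs.cls, outputs.box, outputs.conf, outputs.strides):
        cls_a = cls_m.data[0]  # (nc, H, W)
        box_a = box_m.data[0]
        conf_a = conf_m.data[0, 0]
        nc, hh, ww_ = cls_a.shape
        if image_size is None:
            img_w, img_h = ww_ * s, hh * s
        else:
            img_w, img_h = image_size
        scores = conf_a[None] * cls_a  # (nc, H, W)
        cids, gys, gxs = np.nonzero(scores >= conf_thr)
        for cid, gy, gx in zip(cids, gys, gxs):
            b = decode_box(box_a[:, gy, gx], gy, gx, s).clip(img_w, img_h)
            if b.area <= 0:
                continue
            dets.append(Detection(box=b, score=float(scores[cid, gy, gx]), class_id=int(cid)))
    return nms(dets, iou_thr=iou_thr, score_thr=conf_thr)


# -- target assignment -------------------------------------------------------


@dataclass
class Assignment:
    """Positive-location assignment for one image.

    ``positives`` maps are lists of (level, gy, gx, class_id, Box);
    ``obj_masks`` is one (H, W) 0/1 array per level.
    """

    positives: list[tuple[int, int, int, int, Box]]
    obj_masks: list[np.ndarray]
    strides: tuple[int, ...]


def assign_targets(
    gt: list[tuple[int, Box]],
    level_shapes: list[tuple[int, int]],
    strides: tuple[int, ...] = (8, 16, 32),
    image_size: tuple[int, int] | None = None,
) -> Assignment:
    """Assign each ground-truth box to one positive cell.

    Level choice: nearest ``log2`` stride to the box's nominal stride
    ``sqrt(w*h) / SIZE_GAIN``.  Cell choice: the cell containing the box
    centre; if taken, the 4-neighbourhood, then other levels, and as a
    last resort the centre cell is overwritten.  Guarantees every gt at
    least one positive location.
    """
    if image_size is not None:
        iw, ih = image_size
    else:
        ih = level_shapes[0][0] * strides[0]
        iw = level_shapes[0][1] * strides[0]
    masks = [np.zeros(shape, dtype=np.int64) - 1 for shape in level_shapes]  # -1 = free
    positives: list[tuple[int, int, int, int, Box]] = []

    order = np.argsort([-g[1].area for g in gt])  # big objects first: stabler stealing
    log_strides = np.log2(np.asarray(strides, dtype=np.float64))
    for gi in order:
        cid, box = gt[int(gi)]
        clipped = box.clip(iw, ih)
        if clipped.to_xyxy() != box.to_xyxy():
            warnings.warn("gt box outside image clipped during assignment", stacklevel=2)
            box = clipped
        if box.area <= 0:
            continue
        nominal = max(np.sqrt(box.w * box.h) / SIZE_GAIN, 1e-6)
        pref = np.argsort(np.abs(log_strides - np.log2(nominal)), kind="stable")
        placed = False
        for li in pref:
            s = strides[li]
            hh, ww_ = level_shapes[li]
            gx = min(int(box.xc / s), ww_ - 1)
            gy = min(int(box.yc / s), hh - 1)
            cands = [(gy, gx)]
            if li == pref[0]:  # only the preferred level tries neighbours
                cands += [
                    (gy + dy, gx + dx)
                    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0))
                    if 0 <= gy + dy < hh and 0 <= gx + dx < ww_
                ]
            for cy, cx in cands:
                if masks[li][cy, cx] < 0:
                    masks[li][cy, cx] = len(positives)
                    positives.append((int(li), cy, cx, cid, box))
                    placed = True
                    break
            if placed:
                break
        if not placed:  # overwrite the preferred centre cell
            li = int(pref[0])
            s = strides[li]
            hh, ww_ = level_shapes[li]
            gx = min(int(box.xc / s), ww_ - 1)
            gy = min(int(box.yc / s), hh - 1)
            old = masks[li][gy, gx]
            masks[li][gy, gx] = len(positives)
            positives.append((int(li), gy, gx, cid, box))
            # the displaced gt keeps no cell; acceptable for extreme crowding

    obj_masks = [(m >= 0).astype(np.float64) for m in masks]
    # drop positives that were overwritten
    live = set()
    for li, m in enumerate(masks):
        live.update(int(v) for v in m[m >= 0].ravel())
    positives = [p for i, p in enumerate(positives) if i in live]
    return Assignment(positives=positives, obj_masks=obj_masks, strides=strides)
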