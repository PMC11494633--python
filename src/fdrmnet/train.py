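"""Training loop: Adam with first-moment coefficient 0.937, weight decay
5e-4, multi-step LR decay from 0.01 to 0.001, early stopping on validation
mAP@.5 with 50-epoch patience (all configurable; small-scale runs shrink
epochs/batch but keep the protocol's shape).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import ImageSample, hflip, hsv_jitter
from .evaluate import evaluate_detection
from .geometry import shape_iou_loss_t
from .head import Assignment, HeadOutputs, assign_targets
from .losses import LossConfig, confidence_loss_t, dynamic_focal_loss_t
from .model import FDRMNet
from .nn import Tensor

__all__ = ["TrainConfig", "TrainResult", "detection_loss", "train", "Adam", "SGD", "lr_at_epoch"]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch: int = 16
    optimizer: str = "adam"  # or "sgd"
    lr_initial: float = 0.01
    lr_final: float = 0.001
    lr_milestones: int = 2  # number of multi-step decay points
    momentum: float = 0.937  # Adam beta1 / SGD momentum
    weight_decay: float = 5e-4
    early_stop_patience: int = 50
    seed: int = 0
    conf_thr: float = 0.20  # decode threshold for validation mAP
    iou_thr: float = 0.5
    augment_hflip: bool = False
    augment_hsv: bool = False

    def __post_init__(self):
        if self.lr_final > self.lr_initial:
            raise ValueError("lr_final must be <= lr_initial")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainResult:
    history: list[dict]
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_map: float
    stopped_epoch: int

    def save_history(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.history, indent=1))


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Multi-step decay: k evenly spaced milestones, each multiplying the
    rate by (lr_final/lr_initial)^(1/k); endpoint exactly lr_final."""
    k = cfg.lr_milestones
    if cfg.lr_initial == 0.0:
        return 0.0
    factor = (cfg.lr_final / cfg.lr_initial) ** (1.0 / k) if k else 1.0
    milestones = [int(round(cfg.epochs * (i + 1) / (k + 1))) for i in range(k)]
    n_passed = sum(epoch >= m for m in milestones)
    return cfg.lr_initial * factor**n_passed


class Adam:
    def __init__(self, params, lr=0.01, beta1=0.937, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.mom, self.wd = lr, momentum, weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            b *= self.mom
            b += g
            p.data = p.data - self.lr * b

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def detection_loss(
    outputs: HeadOutputs,
    assignments: list[Assignment],
    cfg: LossConfig | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Composite loss over a batch.

    Class term: mean dynamic focal loss over true-class probabilities at
    positive cells.  Box term: mean shape-aware IoU loss between decoded
    predictions and their gt boxes.  Confidence term: the masked
    squared-error sum per image, averaged over the batch.
    """
    cfg = cfg or LossConfig()
    n_imgs = len(assignments)
    strides = outputs.strides
    nlev = len(strides)

    pt_parts: list[Tensor] = []
    pred_box_parts: list[Tensor] = []
    gt_box_parts: list[np.ndarray] = []
    for li in range(nlev):
        ii, cc, yy, xx, boxes = [], [], [], [], []
        for img_i, asg in enumerate(assignments):
            for (lev, gy, gx, cid, box) in asg.positives:
                if lev != li:
                    continue
                ii.append(img_i)
                cc.append(cid)
                yy.append(gy)
                xx.append(gx)
                boxes.append(box.to_xyxy())
        if not ii:
            continue
        ii = np.asarray(ii)
        cc = np.asarray(cc)
        yy = np.asarray(yy)
        xx = np.asarray(xx)
        pt_parts.append(outputs.cls[li][ii, cc, yy, xx])

        t = outputs.box[li][ii[:, None], np.arange(4)[None, :], yy[:, None], xx[:, None]]
        s = float(strides[li])
        tx, ty = t[:, 0], t[:, 1]
        tw = t[:, 2].clip(-8.0, 8.0)
        th = t[:, 3].clip(-8.0, 8.0)
        from .head import SIZE_GAIN

        cx = (Tensor(xx.astype(np.float32)) + tx.sigmoid()) * s
        cy = (Tensor(yy.astype(np.float32)) + ty.sigmoid()) * s
        bw = tw.exp() * (SIZE_GAIN * s)
        bh = th.exp() * (SIZE_GAIN * s)
        n = len(boxes)
        pred = nn.concat(
            [
                (cx - bw * 0.5).reshape(n, 1),
                (cy - bh * 0.5).reshape(n, 1),
                (cx + bw * 0.5).reshape(n, 1),
                (cy + bh * 0.5).reshape(n, 1),
            ],
            axis=1,
        )
        pred_box_parts.append(pred)
        gt_box_parts.append(np.asarray(boxes, dtype=np.float32))

    if pt_parts:
        pt_all = nn.concat(pt_parts, axis=0) if len(pt_parts) > 1 else pt_parts[0]
        l_cls = dynamic_focal_loss_t(pt_all, cfg)
        pred_all = nn.concat(pred_box_parts, axis=0) if len(pred_box_parts) > 1 else pred_box_parts[0]
        gt_all = np.concatenate(gt_box_parts, axis=0)
        l_box = shape_iou_loss_t(pred_all, gt_all, scale=cfg.scale, theta=cfg.theta)
    else:
        warnings.warn("batch contains no positive assignments")
        l_cls = Tensor(np.float32(0.0))
        l_box = Tensor(np.float32(0.0))

    conf_flat = nn.concat(
        [outputs.conf[li].reshape(n_imgs, -1) for li in range(nlev)], axis=1
    ).reshape(-1)
    obj_flat = np.concatenate(
        [
            np.stack([asg.obj_masks[li] for asg in assignments]).reshape(n_imgs, -1)
            for li in range(nlev)
        ],
        axis=1,
    ).reshape(-1)
    l_conf = confidence_loss_t(conf_flat, obj_flat, obj_flat, cfg) * (1.0 / n_imgs)

    total = cfg.lambda_class * l_cls + cfg.lambda_box * l_box + cfg.lambda_conf * l_conf
    parts = {
        "cls": float(l_cls.data),
        "box": float(l_box.data),
        "conf": float(l_conf.data),
        "total": float(total.data),
    }
    for name, val in parts.items():
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite loss: component '{name}' diverged")
    return total, parts


def _to_batch(samples: list[ImageSample]) -> Tensor:
    arr = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    return Tensor(arr.transpose(0, 3, 1, 2))


def _assign_all(samples: list[ImageSample], level_shapes, strides) -> list[Assignment]:
    return [
        assign_targets(s.labels, level_shapes, strides, image_size=s.size) for s in samples
    ]


def _val_map(model: FDRMNet, val: list[ImageSample], cfg: TrainConfig) -> float:
    preds = [
        model.predict(s.image, conf_thr=cfg.conf_thr, iou_thr=cfg.iou_thr) for s in val
    ]
    gts = [s.labels for s in val]
    return evaluate_detection(preds, gts, iou_thr=0.5).map50


def train(
    model: FDRMNet,
    train_samples: list[ImageSample],
    val_samples: list[ImageSample],
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> TrainResult:
    """Optimize the model; returns history and the best checkpoint by
    validation mAP@.5, with early stopping after ``patience`` epochs
    without improvement."""
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if not train_samples:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)

    h, w = train_samples[0].image.shape[:2]
    strides = model.head.strides
    level_shapes = [(h // s, w // s) for s in strides]

    opt_cls = Adam if cfg.optimizer == "adam" else SGD
    if cfg.optimizer == "adam":
        opt = Adam(model.parameters(), lr=cfg.lr_initial, beta1=cfg.momentum,
                   weight_decay=cfg.weight_decay)
    else:
        opt = SGD(model.parameters(), lr=cfg.lr_initial, momentum=cfg.momentum,
                  weight_decay=cfg.weight_decay)

    history: list[dict] = []
    best_map, best_epoch, best_state = -1.0, -1, copy.deepcopy(model.state_dict())
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(len(train_samples))
        model.train()
        epoch_parts = {"cls": 0.0, "box": 0.0, "conf": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch):
            batch_idx = order[start : start + cfg.batch]
            batch = [train_samples[i] for i in batch_idx]
            if cfg.augment_hflip:
                batch = [hflip(s) if rng.random() < 0.5 else s for s in batch]
            if cfg.augment_hsv:
                batch = [hsv_jitter(s, rng) for s in batch]
            x = _to_batch(batch)
            assignments = _assign_all(batch, level_shapes, strides)
            outputs = model(x)
            total, parts = detection_loss(outputs, assignments, loss_cfg)
            opt.zero_grad()
            total.backward()
            opt.step()
            for k in epoch_parts:
                epoch_parts[k] += parts[k]
            n_batches += 1
        for k in epoch_parts:
            epoch_parts[k] /= max(n_batches, 1)

        model.eval()
        vmap = _val_map(model, val_samples, cfg) if val_samples else 0.0
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": epoch_parts["total"],
                "loss_cls": epoch_parts["cls"],
                "loss_box": epoch_parts["box"],
                "loss_conf": epoch_parts["conf"],
                "val_map50": vmap,
            }
        )
        if vmap > best_map:
            best_map, best_epoch = vmap, epoch
            best_state = copy.deepcopy(model.state_dict())
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break
    stopped = history[-1]["epoch"]
    return TrainResult(
        history=history,
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_map=max(best_map, 0.0),
        stopped_epoch=stopped,
    )
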