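"""Composite detection loss: dynamic focal classification term, shape-aware
IoU box term, and a masked squared-error confidence term.

The total is ``lambda_class * L_class + lambda_box * L_box + lambda_conf *
L_conf`` with default weights (1.0, 5.0, 1.0).  The classification term is a
focal loss whose focusing exponent adapts to the predicted probability:
``gamma_t = gamma0 + (1 - pt) ** beta``.  The confidence term is the masked
sum of squared errors over object / no-object locations with the no-object
sum down-weighted by ``lambda_noobj`` (default 0.5); an optional
binary-cross-entropy variant is available behind ``conf_form="bce"``.

Scalar/ndarray entry points are used by tests and evaluation; the ``*_t``
variants operate on autograd tensors for training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossConfig",
    "ConfidenceTargets",
    "dynamic_focal_loss",
    "classification_loss",
    "confidence_loss",
    "total_loss",
    "dynamic_focal_loss_t",
    "confidence_loss_t",
]

PT_EPS = 1e-7


@dataclass
class LossConfig:
    """All loss hyperparameters.

    Trade-off weights default to (1.0, 5.0, 1.0); the focal balance
    ``alpha`` and dynamic-range exponent ``beta`` default to 0.25 / 1.0.
    """

    lambda_class: float = 1.0
    lambda_box: float = 5.0
    lambda_conf: float = 1.0
    alpha: float = 0.25
    gamma0: float = 2.0
    beta: float = 1.0
    scale: float = 1.0
    theta: float = 4.0
    lambda_noobj: float = 0.5
    conf_form: str = "squared_error"  # or "bce"

    def __post_init__(self):
        for name in ("lambda_class", "lambda_box", "lambda_conf", "gamma0", "lambda_noobj"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.conf_form not in ("squared_error", "bce"):
            raise ValueError("conf_form must be 'squared_error' or 'bce'")


@dataclass
class ConfidenceTargets:
    """Per-prediction confidences, 0/1 targets, and obj/noobj masks."""

    conf: np.ndarray  # C_i in [0,1]
    target: np.ndarray  # \hat C_i in {0,1}
    obj_mask: np.ndarray  # l_i^obj in {0,1}
    noobj_mask: np.ndarray  # l_i^noobj in {0,1}

    def __post_init__(self):
        self.conf = np.asarray(self.conf, dtype=np.float64).reshape(-1)
        self.target = np.asarray(self.target, dtype=np.float64).reshape(-1)
        self.obj_mask = np.asarray(self.obj_mask, dtype=np.float64).reshape(-1)
        self.noobj_mask = np.asarray(self.noobj_mask, dtype=np.float64).reshape(-1)
        n = len(self.conf)
        if not (len(self.target) == len(self.obj_mask) == len(self.noobj_mask) == n):
            raise ValueError("confidence target arrays must share one length")
        if not np.all(self.obj_mask + self.noobj_mask == 1.0):
            raise ValueError("obj and noobj masks must partition every prediction")
        if not np.all((self.target == 1.0) == (self.obj_mask == 1.0)):
            raise ValueError("target must be 1 exactly on obj-masked predictions")

    @property
    def n(self) -> int:
        return len(self.conf)


def dynamic_focal_loss(pt, cfg: LossConfig | None = None) -> np.ndarray | float:
    """Focal loss with probability-adaptive focusing exponent.

    ``-alpha * (1 - pt)^{gamma_t} * log(pt)`` with
    ``gamma_t = gamma0 + (1 - pt)^beta``.  Accepts scalars or arrays.
    """
    cfg = cfg or LossConfig()
    pt_arr = np.asarray(pt, dtype=np.float64)
    if np.any(pt_arr < 0) or np.any(pt_arr > 1):
        raise ValueError("pt must lie in [0, 1]")
    if np.any(pt_arr == 0):
        warnings.warn("pt == 0 clamped to eps to avoid log(0)", stacklevel=2)
        pt_arr = np.maximum(pt_arr, PT_EPS)
    one_m = 1.0 - pt_arr
    gamma_t = cfg.gamma0 + one_m**cfg.beta
    out = -cfg.alpha * one_m**gamma_t * np.log(pt_arr)
    return out if out.ndim else float(out)


def classification_loss(pred_probs, cfg: LossConfig | None = None) -> float:
    """Mean dynamic focal loss over the assigned predictions' true-class
    probabilities.  Empty assignment set -> 0 with a warning."""
    cfg = cfg or LossConfig()
    pt = np.asarray(pred_probs, dtype=np.float64).reshape(-1)
    if pt.size == 0:
        warnings.warn("classification_loss over empty assignment set -> 0", stacklevel=2)
        return 0.0
    return float(np.mean(dynamic_focal_loss(pt, cfg)))


def confidence_loss(ct: ConfidenceTargets, cfg: LossConfig | None = None) -> float:
    """Masked squared-error confidence loss (sum form, as printed)."""
    cfg = cfg or LossConfig()
    sq = (ct.conf - ct.target) ** 2
    if cfg.conf_form == "bce":
        c = np.clip(ct.conf, PT_EPS, 1.0 - PT_EPS)
        sq = -(ct.target * np.log(c) + (1.0 - ct.target) * np.log(1.0 - c))
    return float(np.sum(ct.obj_mask * sq) + cfg.lambda_noobj * np.sum(ct.noobj_mask * sq))


def total_loss(lcls: float, lbox: float, lconf: float, cfg: LossConfig | None = None) -> float:
    """Weighted sum of the three loss components."""
    cfg = cfg or LossConfig()
    if lcls < 0 or lbox < 0 or lconf < 0:
        raise ValueError("loss components must be non-negative")
    return cfg.lambda_class * lcls + cfg.lambda_box * lbox + cfg.lambda_conf * lconf


# -- differentiable variants used by the training loop ----------------------


def dynamic_focal_loss_t(pt: Tensor, cfg: LossConfig | None = None) -> Tensor:
    """Differentiable mean dynamic focal loss over a tensor of pt values."""
    cfg = cfg or LossConfig()
    pt = pt.clip(PT_EPS, 1.0)
    one_m = 1.0 - pt
    gamma_t = cfg.gamma0 + one_m**cfg.beta
    # (1-pt)^{gamma_t} with tensor exponent: exp(gamma_t * log(1-pt))
    focal = (gamma_t * (one_m + PT_EPS).log()).exp()
    return (Tensor(np.float32(-cfg.alpha)) * focal * pt.log()).mean()


def confidence_loss_t(
    conf: Tensor,
    target: np.ndarray,
    obj_mask: np.ndarray,
    cfg: LossConfig | None = None,
) -> Tensor:
    """Differentiable confidence loss on a flat tensor of confidences."""
    cfg = cfg or LossConfig()
    target = np.asarray(target, dtype=np.float32).reshape(-1)
    obj = np.asarray(obj_mask, dtype=np.float32).reshape(-1)
    noobj = 1.0 - obj
    if cfg.conf_form == "bce":
        c = conf.clip(PT_EPS, 1.0 - PT_EPS)
        sq = Tensor(-target) * c.log() - Tensor(1.0 - target) * (1.0 - c).log()
    else:
        sq = (conf - Tensor(target)) ** 2
    return (Tensor(obj) * sq).sum() + cfg.lambda_noobj * (Tensor(noobj) * sq).sum()
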