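"""Full-network assembly, parameter/FLOP accounting, and checkpoints.

``build_model`` wires backbone -> neck -> head from a :class:`ModelConfig`;
the three ablation flags swap in baseline substitutes (plain lateral
pathway for the focus/reconstruction module, C2f for AFFM, independent
decoupled heads for the shared head).

FLOPs are measured by executing a forward pass under the autograd FLOP
meter, with the convention: one fused multiply-add = 2 FLOPs; normalization
and activations counted per element; NMS/post-processing excluded.  Because
the network is fully convolutional, the total is an exact quadratic
polynomial in the input side; :func:`count_flops` evaluates that polynomial
from three small probe sizes, which is bit-for-bit consistent with a direct
metered forward at the target size but far cheaper.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .backbone import Backbone, StageConfig
from .geometry import Detection
from .head import HeadOutputs, IndependentHeads, LPSDH, decode
from .neck import Neck, NeckConfig
from .nn import Module, Tensor

__all__ = [
    "ModelConfig",
    "FDRMNet",
    "build_model",
    "count_parameters",
    "count_flops",
    "summarize",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    backbone: StageConfig = field(default_factory=StageConfig)
    neck: NeckConfig = field(default_factory=NeckConfig)
    head_width: int = 128
    head_depth: int = 2
    num_classes: int = 1
    input_size: int = 640
    use_mffr: bool = True
    use_affm: bool = True
    use_lpsdh: bool = True

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "backbone" in d and isinstance(d["backbone"], dict):
            bb = dict(d["backbone"])
            for k in ("stage_mid", "stage_out"):
                if k in bb:
                    bb[k] = tuple(bb[k])
            d["backbone"] = StageConfig(**bb)
        if "neck" in d and isinstance(d["neck"], dict):
            nk = dict(d["neck"])
            if "affm_hidden" in nk:
                nk["affm_hidden"] = tuple(nk["affm_hidden"])
            d["neck"] = NeckConfig(**nk)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def reference_config() -> ModelConfig:
    """The frozen reference configuration shipped with the package."""
    path = Path(__file__).parent / "configs" / "reference.yaml"
    return ModelConfig.from_yaml(path)


class FDRMNet(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        nk = dataclasses.replace(cfg.neck, use_mffr=cfg.use_mffr, use_affm=cfg.use_affm)
        self.backbone = Backbone(cfg.backbone)
        self.neck = Neck(self.backbone.out_channels, nk)
        head_cls = LPSDH if cfg.use_lpsdh else IndependentHeads
        if self.neck.out_channels[0] != self.neck.out_channels[1]:
            raise ValueError("neck output widths must agree at the head junction")
        self.head = head_cls(
            self.neck.out_channels[0],
            width=cfg.head_width,
            depth=cfg.head_depth,
            nc=cfg.num_classes,
        )

    def forward(self, x: Tensor) -> HeadOutputs:
        s2, s3, s4 = self.backbone(x)
        p3, p4, p5 = self.neck(s2, s3, s4)
        return self.head(p3, p4, p5)

    def predict(
        self,
        image: np.ndarray,
        conf_thr: float = 0.25,
        iou_thr: float = 0.5,
    ) -> list[Detection]:
        """Run inference on one HWC uint8/float image (already sized to a
        multiple of 32) and return post-NMS detections."""
        arr = np.asarray(image)
        if arr.ndim == 3:
            x = arr.astype(np.float32)
            if x.max() > 1.5:
                x = x / 255.0
            x = x.transpose(2, 0, 1)[None]
        else:
            x = arr.astype(np.float32)
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(x))
        if was_training:
            self.train()
        h, w = x.shape[2], x.shape[3]
        return decode(out, conf_thr=conf_thr, iou_thr=iou_thr, image_size=(w, h))


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> FDRMNet:
    """Build the network with seeded, reproducible initial weights."""
    cfg = cfg or reference_config()
    nn.set_rng(seed)
    return FDRMNet(cfg)


def count_parameters(model: Module) -> int:
    """Exact trainable parameter count (shared parameters counted once)."""
    return model.num_parameters()


def _metered_forward_flops(model: FDRMNet, size: int) -> float:
    x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    was_training = model.training
    model.eval()
    with nn.flop_meter() as meter:
        model.forward(x)
    if was_training:
        model.train()
    return meter[0]


def count_flops(model: FDRMNet, input_size: int = 640, exact: bool = False) -> float:
    """Forward-pass FLOPs at ``input_size`` (square RGB input), in GFLOPs.

    With ``exact=True`` the model is run at the full size under the FLOP
    meter.  Otherwise three probe forwards (64/96/128 px) determine the
    quadratic polynomial FLOPs(side) exactly — the network is fully
    convolutional, so per-level feature sizes scale linearly with the
    input side and every primitive's count is a polynomial of degree <= 2
    in the side.
    """
    if input_size % 32:
        raise ValueError("input_size must be divisible by 32")
    if exact:
        return _metered_forward_flops(model, input_size) / 1e9
    probes = (64, 96, 128)
    ys = [_metered_forward_flops(model, s) for s in probes]
    # fit f(s) = a*(s/32)^2 + b*(s/32) + c exactly through 3 points
    xs = np.array([s / 32 for s in probes], dtype=np.float64)
    coeffs = np.linalg.solve(np.vander(xs, 3), np.array(ys, dtype=np.float64))
    return float(np.polyval(coeffs, input_size / 32)) / 1e9


def summarize(cfg: ModelConfig | None = None, seed: int = 0) -> dict:
    """Build the model and report parameter and FLOP totals."""
    model = build_model(cfg, seed=seed)
    n_params = count_parameters(model)
    gflops = count_flops(model, input_size=(cfg or model.cfg).input_size)
    return {
        "params": n_params,
        "params_m": round(n_params / 1e6, 2),
        "gflops": round(gflops, 1),
        "input_size": model.cfg.input_size,
    }


def save_checkpoint(model: FDRMNet, path: str | Path) -> None:
    """Single-file checkpoint: weights + buffers + config + version tag."""
    state = model.state_dict()
    cfg_yaml = yaml.safe_dump(model.cfg.to_dict(), sort_keys=False)
    np.savez(
        path,
        __version__=np.array(CHECKPOINT_VERSION),
        __config__=np.array(cfg_yaml),
        **state,
    )


def load_checkpoint(path: str | Path) -> FDRMNet:
    with np.load(path, allow_pickle=False) as z:
        version = int(z["__version__"])
        if version != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        cfg = ModelConfig.from_dict(yaml.safe_load(str(z["__config__"])))
        model = build_model(cfg, seed=0)
        state = {k: z[k] for k in z.files if not k.startswith("__")}
        model.load_state_dict(state)
    return model
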