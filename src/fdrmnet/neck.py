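"""Feature diffusion-reconstruction neck.

The three backbone features are aligned to stride 16 and concatenated
(focus), processed by parallel depthwise convolutions of kernel sizes
3/5/7/9 whose sum is projected and added residually (reconstruction),
then diffused back to strides 8 and 32, fused with lateral features and
refined by attention-enhanced fusion blocks (AFFM).  Emits P3/P4/P5 at
strides 8/16/32 with a common channel width so the shared head can
consume them.

Ablation substitutes are provided: a plain lateral pathway in place of
the focus/reconstruction module, and the standard C2f block in place of
AFFM at matched widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Conv2d, ConvBNAct, GroupNorm, Module, Parameter, Tensor

__all__ = [
    "NeckConfig",
    "ADown",
    "MFFRFocus",
    "MFFRReconstruct",
    "RepVGGDW",
    "EMAttention",
    "AFFM",
    "C2f",
    "Neck",
]


@dataclass
class NeckConfig:
    branch: int = 64  # per-branch width inside the focus concat
    mid: int = 128  # width of the reconstructed stride-16 trunk
    out: int = 128  # P3/P4/P5 output width (equal across levels)
    affm_hidden: tuple[int, int, int] = (64, 64, 64)  # per-level bottleneck width
    affm_repeats: int = 1
    ema_groups: int = 8
    use_mffr: bool = True
    use_affm: bool = True


def _avg_pool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    """Average pooling via a fixed (non-trainable) depthwise kernel."""
    c = x.shape[1]
    w = Tensor(np.full((c, 1, k, k), 1.0 / (k * k), dtype=np.float32))
    return nn.depthwise_conv2d(x, w, None, stride=stride, padding=padding)


class ADown(Module):
    """2x downsampler: channels split 1:1 into an average-pool + 3x3
    strided-conv branch and a max-pool + pointwise-conv branch."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        if cin % 2 or cout % 2:
            raise ValueError("ADown requires even channel counts")
        self.half = cin // 2
        self.cv1 = ConvBNAct(self.half, cout // 2, 3, stride=2)
        self.cv2 = ConvBNAct(self.half, cout // 2, 1)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise ValueError(f"ADown needs even spatial dims, got {h}x{w}")
        x = _avg_pool2d(x, 2, stride=1, padding=0)  # h-1 x w-1
        x1 = self.cv1(x[:, : self.half])
        x2 = self.cv2(nn.max_pool2d(x[:, self.half :], 3, stride=2, padding=1))
        return nn.concat([x1, x2], axis=1)


class MFFRFocus(Module):
    """Align S2 (down), S3 (lateral 1x1) and S4 (up + 1x1) to stride 16
    and concatenate along channels."""

    def __init__(self, ch: tuple[int, int, int], branch: int):
        super().__init__()
        c2, c3, c4 = ch
        self.down = ADown(c2, branch)
        self.lat = ConvBNAct(c3, branch, 1)
        self.up_conv = ConvBNAct(c4, branch, 1)
        self.out_channels = 3 * branch

    def forward(self, s2: Tensor, s3: Tensor, s4: Tensor) -> Tensor:
        if not (s2.shape[2] == 2 * s3.shape[2] == 4 * s4.shape[2]):
            raise ValueError(
                f"stride mismatch: expected 2:1 ratios, got {s2.shape[2]}/{s3.shape[2]}/{s4.shape[2]}"
            )
        a = self.down(s2)
        b = self.lat(s3)
        c = self.up_conv(nn.upsample_nearest2d(s4, 2))
        return nn.concat([a, b, c], axis=1)


class MFFRReconstruct(Module):
    """Parallel depthwise convs (3/5/7/9) summed, projected by a pointwise
    conv, and added residually to the focused feature."""

    KERNELS = (3, 5, 7, 9)

    def __init__(self, c: int):
        super().__init__()
        self.dws = nn.Sequential(
            *[Conv2d(c, c, k, padding=k // 2, groups=c, bias=True) for k in self.KERNELS]
        )
        self.proj = Conv2d(c, c, 1, bias=True)

    def forward(self, ff: Tensor) -> Tensor:
        acc = None
        for dw in self.dws:
            y = dw(ff)
            acc = y if acc is None else acc + y
        return ff + self.proj(acc)


class RepVGGDW(Module):
    """Depthwise block with 3x3 + 1x1 + identity branches that fuse into a
    single depthwise 3x3 convolution at deploy time."""

    def __init__(self, c: int):
        super().__init__()
        self.c = c
        self.dw3 = Conv2d(c, c, 3, padding=1, groups=c, bias=True)
        self.dw1 = Conv2d(c, c, 1, padding=0, groups=c, bias=True)
        self.deploy = False
        self.fused: Conv2d | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self.deploy:
            return self.fused(x)
        return self.dw3(x) + self.dw1(x) + x

    def reparameterize(self) -> "RepVGGDW":
        """Fuse the three branches into one depthwise 3x3 kernel."""
        w = self.dw3.weight.data.copy()  # (c,1,3,3)
        w[:, :, 1, 1] += self.dw1.weight.data[:, :, 0, 0]  # 1x1 at the centre
        w[:, :, 1, 1] += 1.0  # identity branch
        b = self.dw3.bias.data + self.dw1.bias.data
        fused = Conv2d(self.c, self.c, 3, padding=1, groups=self.c, bias=True)
        fused.weight.data = w
        fused.bias.data = b.copy()
        self.fused = fused
        self.deploy = True
        return self


class EMAttention(Module):
    """Efficient multi-scale attention: grouped directional average pooling
    and convolutions produce sigmoid-bounded gates, and cross spatial
    attention between the gated and conv branches reweights the map."""

    def __init__(self, c: int, groups: int = 8):
        super().__init__()
        if c % groups:
            raise ValueError("channels must be divisible by attention groups")
        self.g = groups
        cg = c // groups
        self.conv1 = Conv2d(cg, cg, 1, bias=True)
        self.conv3 = Conv2d(cg, cg, 3, padding=1, bias=True)
        self.gn = GroupNorm(cg, cg)

    @staticmethod
    def _softmax(x: Tensor, axis: int) -> Tensor:
        shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        cg = c // self.g
        gx = x.reshape(b * self.g, cg, h, w)
        xh = gx.mean(axis=3, keepdims=True)  # (bg, cg, h, 1)
        xw = gx.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (bg, cg, w, 1)
        hw = self.conv1(nn.concat([xh, xw], axis=2))  # (bg, cg, h+w, 1)
        ah = hw[:, :, :h].sigmoid()
        aw = hw[:, :, h:].transpose(0, 1, 3, 2).sigmoid()
        x1 = self.gn(gx * ah * aw)
        x2 = self.conv3(gx)
        x11 = self._softmax(x1.mean(axis=(2, 3)).reshape(b * self.g, 1, cg), axis=2)
        x12 = x2.reshape(b * self.g, cg, h * w)
        x21 = self._softmax(x2.mean(axis=(2, 3)).reshape(b * self.g, 1, cg), axis=2)
        x22 = x1.reshape(b * self.g, cg, h * w)
        weights = (x11 @ x12 + x21 @ x22).reshape(b * self.g, 1, h, w)
        return (gx * weights.sigmoid()).reshape(b, c, h, w)


class _RepBottleneck(Module):
    """AFFM bottleneck: reparameterizable depthwise token mixer, pointwise
    channel mixer, then efficient multi-scale attention."""

    def __init__(self, c: int, ema_groups: int):
        super().__init__()
        self.token = RepVGGDW(c)
        self.mixer = ConvBNAct(c, c, 1)
        self.attn = EMAttention(c, ema_groups)

    def forward(self, x):
        return self.attn(self.mixer(self.token(x)))


class AFFM(Module):
    """Attention-enhanced fusion: pointwise conv, 1:1 channel split, a chain
    of attention bottlenecks on the second half, concat of both halves and
    all bottleneck outputs, pointwise projection."""

    def __init__(self, cin: int, cout: int, hidden: int, n: int = 1, ema_groups: int = 8):
        super().__init__()
        if cin % 2:
            raise ValueError("AFFM input channels must be even for the 1:1 split")
        self.hidden = hidden
        self.n = n
        self.cv1 = ConvBNAct(cin, 2 * hidden, 1)
        self.bottlenecks = nn.Sequential(
            *[_RepBottleneck(hidden, ema_groups) for _ in range(n)]
        )
        self.cv2 = ConvBNAct((2 + n) * hidden, cout, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        s1 = y[:, : self.hidden]
        s2 = y[:, self.hidden :]
        ys = [s1, s2]
        for blk in self.bottlenecks:
            ys.append(blk(ys[-1]))
        return self.cv2(nn.concat(ys, axis=1))


class _DenseBottleneck(Module):
    def __init__(self, c: int):
        super().__init__()
        self.cv1 = ConvBNAct(c, c, 3)
        self.cv2 = ConvBNAct(c, c, 3)

    def forward(self, x):
        return x + self.cv2(self.cv1(x))


class C2f(Module):
    """Baseline dense split/bottleneck block (ablation substitute for AFFM
    at matched channel widths)."""

    def __init__(self, cin: int, cout: int, hidden: int, n: int = 1):
        super().__init__()
        if cin % 2:
            raise ValueError("C2f input channels must be even for the 1:1 split")
        self.hidden = hidden
        self.n = n
        self.cv1 = ConvBNAct(cin, 2 * hidden, 1)
        self.bottlenecks = nn.Sequential(*[_DenseBottleneck(hidden) for _ in range(n)])
        self.cv2 = ConvBNAct((2 + n) * hidden, cout, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        s1 = y[:, : self.hidden]
        s2 = y[:, self.hidden :]
        ys = [s1, s2]
        for blk in self.bottlenecks:
            ys.append(blk(ys[-1]))
        return self.cv2(nn.concat(ys, axis=1))


class Neck(Module):
    """Focus/reconstruct at stride 16, then diffuse to strides 8 and 32 and
    fuse with lateral backbone features; returns (P3, P4, P5)."""

    def __init__(self, in_channels: tuple[int, int, int], cfg: NeckConfig | None = None):
        super().__init__()
        cfg = cfg or NeckConfig()
        self.cfg = cfg
        c2, c3, c4 = in_channels
        fuse = AFFM if cfg.use_affm else C2f

        if cfg.use_mffr:
            self.focus = MFFRFocus(in_channels, cfg.branch)
            self.recon = MFFRReconstruct(self.focus.out_channels)
            self.reduce = ConvBNAct(self.focus.out_channels, cfg.mid, 1)
        else:
            self.reduce = ConvBNAct(c3, cfg.mid, 1)

        self.lat3 = ConvBNAct(c2, cfg.mid, 1)
        self.lat5 = ConvBNAct(c4, cfg.mid, 1)
        self.down5 = ADown(cfg.mid, cfg.mid)
        h3, h4, h5 = cfg.affm_hidden
        kw = {"ema_groups": cfg.ema_groups} if cfg.use_affm else {}
        self.fuse3 = fuse(2 * cfg.mid, cfg.out, h3, cfg.affm_repeats, **kw)
        self.fuse4 = fuse(cfg.mid, cfg.out, h4, cfg.affm_repeats, **kw)
        self.fuse5 = fuse(2 * cfg.mid, cfg.out, h5, cfg.affm_repeats, **kw)
        self.out_channels = (cfg.out, cfg.out, cfg.out)

    def forward(self, s2: Tensor, s3: Tensor, s4: Tensor):
        if self.cfg.use_mffr:
            ff = self.focus(s2, s3, s4)
            mid = self.reduce(self.recon(ff))
        else:
            mid = self.reduce(s3)
        if s2.shape[2] != 2 * mid.shape[2]:
            raise ValueError("level P3: lateral/trunk spatial mismatch")
        if s4.shape[2] * 2 != mid.shape[2]:
            raise ValueError("level P5: lateral/trunk spatial mismatch")
        p3 = self.fuse3(nn.concat([nn.upsample_nearest2d(mid, 2), self.lat3(s2)], axis=1))
        p4 = self.fuse4(mid)
        p5 = self.fuse5(nn.concat([self.down5(mid), self.lat5(s4)], axis=1))
        return p3, p4, p5
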