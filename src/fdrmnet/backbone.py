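"""Four-stage lightweight backbone producing features at strides 8/16/32.

Structure (per stage):

    stage1: HGStem -> HGBlock                (stride 4, internal only)
    stage2: DWConv(s2) -> HGBlock            (stride 8,  S2)
    stage3: DWConv(s2) -> HGBlock x3         (stride 16, S3)
    stage4: DWConv(s2) -> HGBlock -> SPPF    (stride 32, S4)

HGStem mixes small convolutions and pooling at the input; HGBlock stacks
light (pointwise + depthwise) convolutions whose outputs are concatenated
with the block input and squeezed/excited by two pointwise convolutions.
The stride-4 stage-1 output is computed but consumed only as the input to
stage 2; the neck receives S2/S3/S4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .nn import ConvBNAct, Module, Tensor

__all__ = ["StageConfig", "HGStem", "LightConv", "HGBlock", "DWDown", "SPPF", "Backbone"]


@dataclass
class StageConfig:
    """Channel widths and repeat counts for the four backbone stages."""

    stem_mid: int = 24
    stem_out: int = 32
    stage_mid: tuple[int, int, int, int] = (32, 48, 96, 192)
    stage_out: tuple[int, int, int, int] = (64, 128, 256, 512)
    block_convs: int = 3  # light convs per HGBlock
    sppf_k: int = 5

    def __post_init__(self):
        counts = (self.stem_mid, self.stem_out, *self.stage_mid, *self.stage_out,
                  self.block_convs, self.sppf_k)
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all StageConfig counts must be positive integers")


class HGStem(Module):
    """Stride-4 stem: strided conv, a conv branch and a pooling branch
    concatenated, a second strided conv, and a pointwise projection."""

    def __init__(self, cin: int, cm: int, cout: int):
        super().__init__()
        self.stem1 = ConvBNAct(cin, cm, 3, stride=2)
        self.stem2a = ConvBNAct(cm, cm // 2, 3)
        self.stem2b = ConvBNAct(cm // 2, cm, 3)
        self.stem3 = ConvBNAct(2 * cm, cm, 3, stride=2)
        self.stem4 = ConvBNAct(cm, cout, 1)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 4 or w % 4:
            raise ValueError(f"stem input must be divisible by 4, got {h}x{w}")
        x = self.stem1(x)
        branch = self.stem2b(self.stem2a(x))
        pooled = nn.max_pool2d(x, 3, stride=1, padding=1)
        x = self.stem3(nn.concat([pooled, branch], axis=1))
        return self.stem4(x)


class LightConv(Module):
    """Pointwise channel projection followed by a depthwise 3x3."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.pw = ConvBNAct(cin, cout, 1, act=False)
        self.dw = ConvBNAct(cout, cout, 3, groups=cout)

    def forward(self, x):
        return self.dw(self.pw(x))


class HGBlock(Module):
    """n chained light convs; input and all intermediate outputs are
    concatenated then squeezed/excited by two pointwise convs.
    Residual shortcut when in/out widths match."""

    def __init__(self, cin: int, cm: int, cout: int, n: int = 3, shortcut: bool = True):
        super().__init__()
        self.n = n
        self.blocks = nn.Sequential(
            *[LightConv(cin if i == 0 else cm, cm) for i in range(n)]
        )
        self.sc = ConvBNAct(cin + n * cm, cout // 2, 1, act=False)
        self.ec = ConvBNAct(cout // 2, cout, 1, act=False)
        self.add = shortcut and cin == cout

    def forward(self, x):
        ys = [x]
        for blk in self.blocks:
            ys.append(blk(ys[-1]))
        y = self.ec(self.sc(nn.concat(ys, axis=1)))
        return y + x if self.add else y


class DWDown(Module):
    """Depthwise 3x3 stride-2 downsampler (channel count preserved)."""

    def __init__(self, c: int):
        super().__init__()
        self.dw = ConvBNAct(c, c, 3, stride=2, groups=c)

    def forward(self, x):
        return self.dw(x)


class SPPF(Module):
    """Serial max-pool pyramid: three chained k-pools concatenated with the
    input projection, equivalent to parallel pools of size k, 2k-1, 3k-2."""

    def __init__(self, cin: int, cout: int, k: int = 5):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("SPPF pool size must be odd")
        self.k = k
        ch = cin // 2
        self.cv1 = ConvBNAct(cin, ch, 1)
        self.cv2 = ConvBNAct(4 * ch, cout, 1)

    def forward(self, x):
        x = self.cv1(x)
        p = self.k // 2
        y1 = nn.max_pool2d(x, self.k, stride=1, padding=p)
        y2 = nn.max_pool2d(y1, self.k, stride=1, padding=p)
        y3 = nn.max_pool2d(y2, self.k, stride=1, padding=p)
        return self.cv2(nn.concat([x, y1, y2, y3], axis=1))


class Backbone(Module):
    """HGNet-v2-style extractor; returns (S2, S3, S4) at strides 8/16/32."""

    def __init__(self, cfg: StageConfig | None = None):
        super().__init__()
        cfg = cfg or StageConfig()
        self.cfg = cfg
        m = cfg.stage_mid
        c = cfg.stage_out
        n = cfg.block_convs
        self.stem = HGStem(3, cfg.stem_mid, cfg.stem_out)
        self.block1 = HGBlock(cfg.stem_out, m[0], c[0], n=n)
        self.down2 = DWDown(c[0])
        self.block2 = HGBlock(c[0], m[1], c[1], n=n)
        self.down3 = DWDown(c[1])
        self.block3 = nn.Sequential(
            HGBlock(c[1], m[2], c[2], n=n),
            HGBlock(c[2], m[2], c[2], n=n),
            HGBlock(c[2], m[2], c[2], n=n),
        )
        self.down4 = DWDown(c[2])
        self.block4 = HGBlock(c[2], m[3], c[3], n=n)
        self.sppf = SPPF(c[3], c[3], k=cfg.sppf_k)
        self.out_channels = (c[1], c[2], c[3])

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"backbone input dims must be divisible by 32, got {h}x{w}")
        f1 = self.block1(self.stem(x))  # stride 4, internal intermediate
        s2 = self.block2(self.down2(f1))  # stride 8
        s3 = self.block3(self.down3(s2))  # stride 16
        s4 = self.sppf(self.block4(self.down4(s3)))  # stride 32
        return s2, s3, s4
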