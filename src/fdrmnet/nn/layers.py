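"""Neural-network layers on top of the autograd primitives."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "set_rng",
    "get_rng",
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "GroupNorm",
    "SiLU",
    "Sigmoid",
    "Identity",
    "ConvBNAct",
]

_RNG = np.random.default_rng(0)


def set_rng(seed: int) -> None:
    """Seed the RNG used for all subsequent layer weight initialisation."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container: parameter registration, train/eval mode,
    flat state_dict for checkpointing."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield f"{prefix}{n}", p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{n}.")

    def parameters(self) -> list[Parameter]:
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:  # shared parameters are counted once
                seen.add(id(p))
                out.append(p)
        return out

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for n, p in self._params.items():
            out[f"{prefix}{n}"] = p.data
        for n, b in self._buffers.items():
            out[f"{prefix}{n}"] = np.asarray(b)
        for n, m in self._modules.items():
            out.update(m.state_dict(prefix=f"{prefix}{n}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for n, p in self._params.items():
            key = f"{prefix}{n}"
            arr = np.asarray(state[key], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for n in list(self._buffers):
            key = f"{prefix}{n}"
            if key in state:
                self._set_buffer(n, np.asarray(state[key]).copy())
        for n, m in self._modules.items():
            m.load_state_dict(state, prefix=f"{prefix}{n}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Conv2d(Module):
    """2-D convolution; groups must be 1 (dense) or == in_channels (depthwise)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 1,
        stride: int = 1,
        padding: int | None = None,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if groups not in (1, cin):
            raise ValueError("groups must be 1 or in_channels")
        if groups == cin and cout != cin:
            raise ValueError("depthwise conv requires cout == cin")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        bound = 1.0 / np.sqrt(fan_in)
        wshape = (cout, cin // groups, k, k)
        self.weight = Parameter(_RNG.uniform(-bound, bound, size=wshape))
        self.bias = Parameter(_RNG.uniform(-bound, bound, size=(cout,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.groups == 1:
            return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)
        return ag.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer(
                "running_mean",
                ((1 - m) * self.running_mean + m * mu.data.reshape(-1)).astype(np.float32),
            )
            self._set_buffer(
                "running_var",
                ((1 - m) * self.running_var + m * var.data.reshape(-1)).astype(np.float32),
            )
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, self.c, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, self.c, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(std)
        return xhat * self.gamma.reshape(1, self.c, 1, 1) + self.beta.reshape(1, self.c, 1, 1)


class GroupNorm(Module):
    def __init__(self, num_groups: int, c: int, eps: float = 1e-5):
        super().__init__()
        if c % num_groups:
            raise ValueError("channels must divide into groups")
        self.g, self.c, self.eps = num_groups, c, eps
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        xg = x.reshape(n, self.g, c // self.g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=(2, 3, 4), keepdims=True)
        xhat = ((xg - mu) / ((var + self.eps) ** 0.5)).reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ConvBNAct(Module):
    """Conv -> BatchNorm -> SiLU, the basic block used throughout."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, groups=1, act=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
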