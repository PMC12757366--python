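"""Layer modules: parameter containers with a torch-like Module tree."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor, concat

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Seed the global initializer RNG (weight init determinism)."""
    global _rng
    _rng = np.random.default_rng(seed)


def uniform_param(shape, bound: float) -> Tensor:
    return Tensor(_rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, ModuleList):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({"buf." + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data[...] = d[n]
        for n, b in self.named_buffers():
            b[...] = d["buf." + n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Conv2d(Module):
    """Plain convolution (optionally biased), torch-style fan-in init."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = c_in * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = uniform_param((c_out, c_in, k, k), bound)
        self.bias = uniform_param((c_out,), bound) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.03, eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(c), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class ConvBnSiLU(Module):
    """Conv + BatchNorm + SiLU, the detector's standard convolution unit."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, padding, bias=False)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    def __init__(self, c_in: int, c_out: int, shortcut: bool = True):
        super().__init__()
        c_mid = c_out
        self.cv1 = ConvBnSiLU(c_in, c_mid, 1)
        self.cv2 = ConvBnSiLU(c_mid, c_out, 3)
        self.add = shortcut and c_in == c_out

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """Cross-stage-partial block with n bottlenecks."""

    def __init__(self, c_in: int, c_out: int, n: int = 1, shortcut: bool = True):
        super().__init__()
        c_mid = c_out // 2
        self.cv1 = ConvBnSiLU(c_in, c_mid, 1)
        self.cv2 = ConvBnSiLU(c_in, c_mid, 1)
        self.cv3 = ConvBnSiLU(2 * c_mid, c_out, 1)
        self.m = ModuleList([Bottleneck(c_mid, c_mid, shortcut) for _ in range(n)])

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(concat([y, self.cv2(x)], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c_in: int, c_out: int, k: int = 5):
        super().__init__()
        c_mid = c_in // 2
        self.k = k
        self.cv1 = ConvBnSiLU(c_in, c_mid, 1)
        self.cv2 = ConvBnSiLU(4 * c_mid, c_out, 1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = F.max_pool2d(y, self.k, 1, self.k // 2)
        p2 = F.max_pool2d(p1, self.k, 1, self.k // 2)
        p3 = F.max_pool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(concat([y, p1, p2, p3], axis=1))


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_nearest2x(x)
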