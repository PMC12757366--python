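"""Enhanced Spatial Attention (ESA).

The block computes a single-channel spatial attention map from multi-scale
convolutional descriptors of the incoming feature map and uses it to gate
the features residually:

    D3 = SiLU(conv3x3(F)),  D5 = SiLU(conv5x5(F))
    S  = sigmoid(conv1x1([D3; D5]))          # one channel, values in (0,1)
    F' = F + alpha * (F * S)                 # alpha is a learnable scalar

With ``alpha = 0`` the block is the identity, which makes its contribution
separable in ablations.  A ``sequential`` variant replaces the parallel
descriptors with a chain of three 3x3 convolutions through a channel
bottleneck (reduction ``r_seq``), producing the map
``S = sigmoid(f3(SiLU(f2(SiLU(f1(F))))))``.

Functional entry points (:func:`spatial_descriptors`, :func:`attention_map`,
:func:`esa_forward`) operate on plain ``[C, H, W]`` numpy arrays; the
:class:`ESA` module is the trainable counterpart used inside the detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F


class ConfigurationError(ValueError):
    pass


def silu(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return x / (1.0 + np.exp(-x))


def sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def esa_param_count(c_in: int, c3: int, c5: int) -> int:
    """Trainable scalars of the parallel ESA block.

    Both biased descriptor convolutions, the biased 1x1 fusion convolution
    and the scalar gate:
    ``(9*c_in*c3 + c3) + (25*c_in*c5 + c5) + (c3 + c5 + 1) + 1``.
    """
    if c_in <= 0 or c3 <= 0 or c5 <= 0:
        raise ValueError("esa_param_count requires positive channel counts")
    return (9 * c_in * c3 + c3) + (25 * c_in * c5 + c5) + (c3 + c5 + 1) + 1


@dataclass
class ESAParams:
    """Weights of one ESA block, held as plain numpy arrays.

    Parallel variant: ``w3 [c3,C,3,3]``, ``w5 [c5,C,5,5]``,
    ``w_fuse [1,c3+c5,1,1]`` with biases, scalar ``alpha``.
    Sequential variant instead carries ``seq_w1/2/3`` (all 3x3) through a
    ``C -> C/r_seq`` bottleneck down to one channel.
    """

    w3: np.ndarray
    b3: np.ndarray
    w5: np.ndarray
    b5: np.ndarray
    w_fuse: np.ndarray
    b_fuse: np.ndarray
    alpha: float = 1.0
    variant: str = "parallel"
    r_seq: int = 16
    seq_w1: np.ndarray | None = None
    seq_b1: np.ndarray | None = None
    seq_w2: np.ndarray | None = None
    seq_b2: np.ndarray | None = None
    seq_w3: np.ndarray | None = None
    seq_b3: np.ndarray | None = None

    def __post_init__(self):
        if self.variant not in ("parallel", "sequential"):
            raise ConfigurationError(f"unknown ESA variant {self.variant!r}")
        if self.c3 <= 0 or self.c5 <= 0:
            raise ConfigurationError("ESA branch widths must be positive")
        if not np.isfinite(self.alpha):
            raise ConfigurationError("ESA gate alpha must be finite")

    @property
    def c_in(self) -> int:
        return self.w3.shape[1]

    @property
    def c3(self) -> int:
        return self.w3.shape[0]

    @property
    def c5(self) -> int:
        return self.w5.shape[0]

    def count(self) -> int:
        """Number of stored trainable scalars (parallel branch weights)."""
        return (self.w3.size + self.b3.size + self.w5.size + self.b5.size
                + self.w_fuse.size + self.b_fuse.size + 1)

    @classmethod
    def init(cls, c_in: int, c3: int = 64, c5: int = 24,
             variant: str = "parallel", r_seq: int = 16,
             rng: np.random.Generator | None = None) -> "ESAParams":
        """Fresh weights: descriptor convs fan-in uniform, fusion conv
        small symmetric noise with zero bias (map starts near 0.5),
        alpha = 1."""
        rng = rng or np.random.default_rng(0)
        def u(shape, fan_in):
            b = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-b, b, size=shape).astype(np.float32)
        p = cls(
            w3=u((c3, c_in, 3, 3), 9 * c_in), b3=np.zeros(c3, np.float32),
            w5=u((c5, c_in, 5, 5), 25 * c_in), b5=np.zeros(c5, np.float32),
            w_fuse=(rng.normal(0, 0.01, size=(1, c3 + c5, 1, 1)).astype(np.float32)),
            b_fuse=np.zeros(1, np.float32),
            alpha=1.0, variant=variant, r_seq=r_seq,
        )
        if variant == "sequential":
            c_mid = max(c_in // r_seq, 1)
            p.seq_w1 = u((c_mid, c_in, 3, 3), 9 * c_in)
            p.seq_b1 = np.zeros(c_mid, np.float32)
            p.seq_w2 = u((c_mid, c_mid, 3, 3), 9 * c_mid)
            p.seq_b2 = np.zeros(c_mid, np.float32)
            p.seq_w3 = np.zeros((1, c_mid, 3, 3), np.float32)
            p.seq_b3 = np.zeros(1, np.float32)
        return p


def _check_channels(fmap: np.ndarray, params: ESAParams) -> None:
    if fmap.ndim != 3:
        raise ConfigurationError(f"feature map must be [C,H,W], got shape {fmap.shape}")
    if fmap.shape[0] != params.c_in:
        raise ConfigurationError(
            f"channel mismatch: ESA expects {params.c_in} input channels, "
            f"feature map has {fmap.shape[0]}")
    if not np.isfinite(fmap).all():
        raise ValueError("feature map contains non-finite values")


def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, pad: int) -> np.ndarray:
    with nn.no_grad():
        out = F.conv2d(Tensor(x[None]), Tensor(w), Tensor(b), 1, pad)
    return out.data[0]


def spatial_descriptors(fmap: np.ndarray, params: ESAParams
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-scale descriptors: same-padded 3x3 and 5x5 convs + SiLU."""
    _check_channels(fmap, params)
    if params.variant != "parallel":
        raise ConfigurationError("spatial_descriptors applies to the parallel variant")
    d3 = silu(_conv(fmap, params.w3, params.b3, 1))
    d5 = silu(_conv(fmap, params.w5, params.b5, 2))
    return d3, d5


def attention_map(fmap: np.ndarray, params: ESAParams) -> np.ndarray:
    """Single-channel sigmoid attention map ``S = sigmoid(fuse([D3; D5]))``."""
    d3, d5 = spatial_descriptors(fmap, params)
    fused = _conv(np.concatenate([d3, d5], axis=0), params.w_fuse, params.b_fuse, 0)
    return sigmoid(fused)


def esa_forward(fmap: np.ndarray, params: ESAParams) -> np.ndarray:
    """Gated residual recalibration ``F' = F + alpha * (F * S)``."""
    _check_channels(fmap, params)
    if params.variant == "parallel":
        s = attention_map(fmap, params)
    else:
        h = silu(_conv(fmap, params.seq_w1, params.seq_b1, 1))
        h = silu(_conv(h, params.seq_w2, params.seq_b2, 1))
        s = sigmoid(_conv(h, params.seq_w3, params.seq_b3, 1))
    return fmap + params.alpha * (fmap * s)


class ESA(nn.Module):
    """Trainable ESA block (see module docstring for the math)."""

    def __init__(self, c_in: int, c3: int = 64, c5: int = 24,
                 variant: str = "parallel", r_seq: int = 16):
        super().__init__()
        if variant not in ("parallel", "sequential"):
            raise ConfigurationError(f"unknown ESA variant {variant!r}")
        self.c_in, self.c3, self.c5 = c_in, c3, c5
        self.variant = variant
        self.alpha = Tensor(np.ones(()), requires_grad=True)
        if variant == "parallel":
            self.conv3 = nn.Conv2d(c_in, c3, 3)
            self.conv5 = nn.Conv2d(c_in, c5, 5)
            self.fuse = nn.Conv2d(c3 + c5, 1, 1)
            # near-neutral start: S ~ 0.5 everywhere
            self.fuse.weight.data[...] = np.random.default_rng(0).normal(
                0, 0.01, self.fuse.weight.shape).astype(np.float32)
            self.fuse.bias.data[...] = 0.0
            self.conv3.bias.data[...] = 0.0
            self.conv5.bias.data[...] = 0.0
        else:
            c_mid = max(c_in // r_seq, 1)
            self.f1 = nn.Conv2d(c_in, c_mid, 3)
            self.f2 = nn.Conv2d(c_mid, c_mid, 3)
            self.f3 = nn.Conv2d(c_mid, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        if self.variant == "parallel":
            d3 = self.conv3(x).silu()
            d5 = self.conv5(x).silu()
            s = self.fuse(nn.concat([d3, d5], axis=1)).sigmoid()
        else:
            s = self.f3(self.f2(self.f1(x).silu()).silu()).sigmoid()
        return x + self.alpha * (x * s)

    def export_params(self) -> ESAParams:
        """Snapshot the module weights as an :class:`ESAParams`."""
        if self.variant == "parallel":
            return ESAParams(
                w3=self.conv3.weight.data.copy(), b3=self.conv3.bias.data.copy(),
                w5=self.conv5.weight.data.copy(), b5=self.conv5.bias.data.copy(),
                w_fuse=self.fuse.weight.data.copy(), b_fuse=self.fuse.bias.data.copy(),
                alpha=float(self.alpha.data))
        p = ESAParams.init(self.c_in, self.c3, self.c5, variant="sequential")
        p.alpha = float(self.alpha.data)
        p.seq_w1, p.seq_b1 = self.f1.weight.data.copy(), self.f1.bias.data.copy()
        p.seq_w2, p.seq_b2 = self.f2.weight.data.copy(), self.f2.bias.data.copy()
        p.seq_w3, p.seq_b3 = self.f3.weight.data.copy(), self.f3.bias.data.copy()
        return p
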