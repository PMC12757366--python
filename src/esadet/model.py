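"""YOLOv5m-style detector graph with configurable ESA placement.

The network is the release-6 dialect of the medium YOLOv5 detector: a 6x6
stride-2 stem, four Conv+C3 backbone stages with base repeats (3, 6, 9, 3)
scaled by ``depth_multiple``, base widths (64, 128, 256, 512, 1024) scaled
by ``width_multiple`` (rounded up to multiples of 8), an SPPF bottleneck, a
CSP-PAN neck and three 1x1 detection convolutions at strides 8/16/32.  The
ESA block can be spliced immediately before or after SPPF (both positions
see the 768-channel width at ``width_multiple = 0.75``).
"""

from __future__ import annotations

import io
import math
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import nn
from .attention import ESA
from .nn import Tensor

STOCK_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)

PLACEMENTS = ("none", "before_sppf", "after_sppf")


def make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


@dataclass
class DetectorConfig:
    placement: str = "after_sppf"
    num_classes: int = 3
    depth_multiple: float = 0.67
    width_multiple: float = 0.75
    img_size: int = 640
    anchors: tuple = STOCK_ANCHORS
    strides: tuple = (8, 16, 32)
    esa_c3: int = 64
    esa_c5: int = 24
    esa_variant: str = "parallel"

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        if self.img_size % 32 != 0:
            raise ValueError(f"img_size must be divisible by 32, got {self.img_size}")
        if len(self.anchors) != 3 or len(self.strides) != 3:
            raise ValueError("expected 3 anchor scales and 3 strides")

    def width(self, c: int) -> int:
        return make_divisible(c * self.width_multiple)

    def depth(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1)

    def anchor_array(self) -> np.ndarray:
        """[3, 3, 2] anchor priors in pixels at the input resolution.

        The stock defaults suit 640-pixel inputs; for other resolutions or
        atypical object-size distributions fit them to the labels with
        :func:`esadet.train.fit_anchors`.
        """
        return np.asarray(self.anchors, dtype=np.float32)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["anchors"] = [[list(a) for a in s] for s in self.anchors]
        d["strides"] = list(self.strides)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DetectorConfig":
        d = yaml.safe_load(text)
        d["anchors"] = tuple(tuple(tuple(a) for a in s) for s in d["anchors"])
        d["strides"] = tuple(d["strides"])
        return cls(**d)


@dataclass
class LayerSpec:
    """Declarative record of one graph node (for inspection/serialization)."""
    kind: str
    frm: tuple[int, ...]   # producer indices (-1 = previous layer)
    c_out: int


class Detector(nn.Module):
    """The assembled detector; ``spec`` mirrors the module list declaratively."""

    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        self.cfg = cfg
        w, d = cfg.width, cfg.depth
        c64, c128, c256, c512, c1024 = (w(c) for c in (64, 128, 256, 512, 1024))
        nc = cfg.num_classes
        self.no = 5 + nc

        layers: list[nn.Module] = []
        spec: list[LayerSpec] = []

        def add(kind, module, frm=(-1,), c_out=0):
            layers.append(module)
            spec.append(LayerSpec(kind, tuple(frm), c_out))
            return len(layers) - 1

        add("conv", nn.ConvBnSiLU(3, c64, 6, 2, padding=2), c_out=c64)
        add("conv", nn.ConvBnSiLU(c64, c128, 3, 2), c_out=c128)
        add("c3", nn.C3(c128, c128, d(3)), c_out=c128)
        add("conv", nn.ConvBnSiLU(c128, c256, 3, 2), c_out=c256)
        i_p3 = add("c3", nn.C3(c256, c256, d(6)), c_out=c256)
        add("conv", nn.ConvBnSiLU(c256, c512, 3, 2), c_out=c512)
        i_p4 = add("c3", nn.C3(c512, c512, d(9)), c_out=c512)
        add("conv", nn.ConvBnSiLU(c512, c1024, 3, 2), c_out=c1024)
        add("c3", nn.C3(c1024, c1024, d(3)), c_out=c1024)
        if cfg.placement == "before_sppf":
            add("esa", ESA(c1024, cfg.esa_c3, cfg.esa_c5, cfg.esa_variant), c_out=c1024)
        add("sppf", nn.SPPF(c1024, c1024), c_out=c1024)
        if cfg.placement == "after_sppf":
            add("esa", ESA(c1024, cfg.esa_c3, cfg.esa_c5, cfg.esa_variant), c_out=c1024)

        i_n1 = add("conv", nn.ConvBnSiLU(c1024, c512, 1, 1), c_out=c512)
        add("upsample", nn.Upsample2x(), c_out=c512)
        add("concat", _Concat(), frm=(-1, i_p4), c_out=c1024)
        add("c3", nn.C3(c1024, c512, d(3), shortcut=False), c_out=c512)
        i_n2 = add("conv", nn.ConvBnSiLU(c512, c256, 1, 1), c_out=c256)
        add("upsample", nn.Upsample2x(), c_out=c256)
        add("concat", _Concat(), frm=(-1, i_p3), c_out=c512)
        i_out3 = add("c3", nn.C3(c512, c256, d(3), shortcut=False), c_out=c256)
        add("conv", nn.ConvBnSiLU(c256, c256, 3, 2), c_out=c256)
        add("concat", _Concat(), frm=(-1, i_n2), c_out=c512)
        i_out4 = add("c3", nn.C3(c512, c512, d(3), shortcut=False), c_out=c512)
        add("conv", nn.ConvBnSiLU(c512, c512, 3, 2), c_out=c512)
        add("concat", _Concat(), frm=(-1, i_n1), c_out=c1024)
        i_out5 = add("c3", nn.C3(c1024, c1024, d(3), shortcut=False), c_out=c1024)

        self.layers = nn.ModuleList(layers)
        self.spec = spec
        self.out_indices = (i_out3, i_out4, i_out5)
        self.head = nn.ModuleList([
            nn.Conv2d(c, 3 * self.no, 1, bias=True)
            for c in (c256, c512, c1024)
        ])
        self._init_head_biases()
        self._needed = self._compute_needed()
        self.sppf_channels = c1024

    # class-frequency prior on head biases stabilizes early objectness
    def _init_head_biases(self) -> None:
        nc = self.cfg.num_classes
        for conv, s in zip(self.head, self.cfg.strides):
            b = conv.bias.data.reshape(3, self.no)
            b[:, 4] += math.log(8.0 / (self.cfg.img_size / s) ** 2)
            b[:, 5:] += math.log(0.6 / (nc - 0.99)) if nc > 1 else 0.0
            conv.bias.data[...] = b.reshape(-1)

    def _compute_needed(self) -> set[int]:
        needed = set(self.out_indices)
        for i, ls in enumerate(self.spec):
            for f in ls.frm:
                if f != -1:
                    needed.add(f)
        return needed

    def forward(self, x: Tensor | np.ndarray) -> list[Tensor]:
        """Run the graph; returns per-scale ``[B, 3, H/s, W/s, 5+nc]`` tensors."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected [B,3,H,W] input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(
                f"spatial size {x.shape[2:]} must be divisible by 32")
        saved: dict[int, Tensor] = {}
        y = x
        for i, (module, ls) in enumerate(zip(self.layers, self.spec)):
            if ls.kind == "concat":
                inputs = [y if f == -1 else saved[f] for f in ls.frm]
                y = module(inputs)
            else:
                y = module(y)
            if i in self._needed:
                saved[i] = y
        outs = []
        for idx, conv in zip(self.out_indices, self.head):
            p = conv(saved[idx])
            b, _, h, wdt = p.shape
            outs.append(p.reshape(b, 3, self.no, h, wdt).transpose(0, 1, 3, 4, 2))
        return outs

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        """Checkpoint: zlib-compressed npz-style blob with embedded config."""
        state = self.state_dict()
        buf = io.BytesIO()
        np.savez(buf, __config__=np.frombuffer(
            self.cfg.to_yaml().encode(), dtype=np.uint8), **state)
        with open(path, "wb") as f:
            f.write(zlib.compress(buf.getvalue(), 1))

    @classmethod
    def load(cls, path) -> "Detector":
        with open(path, "rb") as f:
            raw = zlib.decompress(f.read())
        data = np.load(io.BytesIO(raw))
        cfg = DetectorConfig.from_yaml(bytes(data["__config__"]).decode())
        model = build_detector(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


class _Concat(nn.Module):
    def forward(self, xs: list[Tensor]) -> Tensor:
        return nn.concat(xs, axis=1)


def build_detector(cfg: DetectorConfig) -> Detector:
    """Assemble the detector graph for a configuration."""
    model = Detector(cfg)
    _validate_graph(model)
    return model


def _validate_graph(model: Detector) -> None:
    kinds = [ls.kind for ls in model.spec]
    assert kinds.count("sppf") == 1, "graph must contain exactly one SPPF"
    i_sppf = kinds.index("sppf")
    if model.cfg.placement == "none":
        assert "esa" not in kinds
    elif model.cfg.placement == "before_sppf":
        assert kinds[i_sppf - 1] == "esa"
    else:
        assert kinds[i_sppf + 1] == "esa"


def count_parameters(model: Detector) -> int:
    """Total trainable scalars (conv weights/biases, BN affine, ESA weights)."""
    return model.num_parameters()


@dataclass
class RawPrediction:
    """Per-scale head outputs as numpy arrays ``[B,3,H,W,5+nc]``."""
    scales: list[np.ndarray]

    @classmethod
    def from_tensors(cls, outs: list[Tensor]) -> "RawPrediction":
        return cls([o.data for o in outs])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def decode_predictions(raw, cfg: DetectorConfig, conf_threshold: float = 0.25,
                       image_id: str = "") -> list:
    """Decode raw head outputs of one image into scored detections.

    Per anchor/cell: ``xy = (2*sigmoid(t_xy) - 0.5 + grid) * stride``,
    ``wh = (2*sigmoid(t_wh))^2 * anchor``; the reported class is the best
    class and its score ``sigmoid(obj) * sigmoid(cls)``.  Boxes are clipped
    to the image bounds.
    """
    from .metrics import Detection

    scales = raw.scales if isinstance(raw, RawPrediction) else raw
    anchors = cfg.anchor_array()
    dets: list[Detection] = []
    for s_idx, (p, stride) in enumerate(zip(scales, cfg.strides)):
        if p.ndim == 5:          # [B,3,H,W,no] -> first image
            p = p[0]
        na, h, w, _ = p.shape
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        sig = _sigmoid(p)
        xy_x = (2.0 * sig[..., 0] - 0.5 + gx) * stride
        xy_y = (2.0 * sig[..., 1] - 0.5 + gy) * stride
        ww = (2.0 * sig[..., 2]) ** 2 * anchors[s_idx, :, 0][:, None, None]
        hh = (2.0 * sig[..., 3]) ** 2 * anchors[s_idx, :, 1][:, None, None]
        obj = sig[..., 4]
        cls = sig[..., 5:]
        best = cls.argmax(axis=-1)
        score = obj * np.take_along_axis(cls, best[..., None], axis=-1)[..., 0]
        keep = np.argwhere(score >= conf_threshold)
        bound = cfg.img_size
        for a, gy_i, gx_i in keep:
            cx, cy = xy_x[a, gy_i, gx_i], xy_y[a, gy_i, gx_i]
            bw, bh = ww[a, gy_i, gx_i], hh[a, gy_i, gx_i]
            x1 = float(np.clip(cx - bw / 2, 0, bound))
            y1 = float(np.clip(cy - bh / 2, 0, bound))
            x2 = float(np.clip(cx + bw / 2, 0, bound))
            y2 = float(np.clip(cy + bh / 2, 0, bound))
            if x2 <= x1 or y2 <= y1:
                continue
            dets.append(Detection(
                box=(x1, y1, x2, y2),
                score=float(score[a, gy_i, gx_i]),
                class_id=int(best[a, gy_i, gx_i]),
                image_id=image_id))
    return dets
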