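"""Dataset I/O and the preprocessing/augmentation stack.

Images are carried as float32 ``[3, H, W]`` arrays in [0, 1]; labels as
normalized center-format boxes (the YOLO txt convention
``class xc yc w h``).  The training transform is
normalize -> letterbox-resize -> augment, with flip / rotation / HSV jitter /
mosaic / mixup applied to the training split only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

PAD_VALUE = 114.0 / 255.0
CLASS_NAMES = ["glioma", "meningioma", "pituitary"]
MIN_BOX_AREA_FRAC = 0.10   # drop boxes clipped below 10% of original area
MIN_BOX_SIDE_PX = 2.0


class LabelParseError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedBox:
    xc: float
    yc: float
    w: float
    h: float
    class_id: int

    def __post_init__(self):
        for name in ("xc", "yc", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")

    def corners(self, width: float = 1.0, height: float = 1.0):
        return ((self.xc - self.w / 2) * width, (self.yc - self.h / 2) * height,
                (self.xc + self.w / 2) * width, (self.yc + self.h / 2) * height)


@dataclass
class LabeledImage:
    image: np.ndarray                  # [3, H, W] float32 in [0, 1]
    boxes: list[NormalizedBox]
    source_id: str = ""


def clip_box(x1, y1, x2, y2, class_id, orig_area=None) -> NormalizedBox | None:
    """Clip normalized corners to the unit square; apply the drop policy."""
    cx1, cy1 = max(x1, 0.0), max(y1, 0.0)
    cx2, cy2 = min(x2, 1.0), min(y2, 1.0)
    w, h = cx2 - cx1, cy2 - cy1
    if w <= 0 or h <= 0:
        return None
    if orig_area is not None and w * h < MIN_BOX_AREA_FRAC * orig_area:
        return None
    return NormalizedBox((cx1 + cx2) / 2, (cy1 + cy2) / 2, w, h, class_id)


# ------------------------------------------------------------------ label IO
def read_yolo_labels(path, num_classes: int | None = None) -> list[NormalizedBox]:
    boxes = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                xc, yc, w, h = (float(v) for v in parts[1:])
            except ValueError as e:
                raise LabelParseError(f"{path}:{lineno}: {e}") from None
            if num_classes is not None and not 0 <= cid < num_classes:
                raise LabelParseError(f"{path}:{lineno}: class {cid} out of range")
            try:
                boxes.append(NormalizedBox(xc, yc, w, h, cid))
            except ValueError as e:
                raise LabelParseError(f"{path}:{lineno}: {e}") from None
    return boxes


def write_yolo_labels(boxes: list[NormalizedBox], path) -> None:
    with open(path, "w") as f:
        for b in boxes:
            f.write(f"{b.class_id} {b.xc:.6f} {b.yc:.6f} {b.w:.6f} {b.h:.6f}\n")


# ------------------------------------------------------------- preprocessing
def _to_chw(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 2:
        img = np.stack([img] * 3)
    elif img.ndim == 3 and img.shape[-1] in (1, 3):
        img = np.moveaxis(img, -1, 0)
        if img.shape[0] == 1:
            img = np.concatenate([img] * 3)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError(f"cannot interpret image of shape {img.shape}")
    return img


def normalize_and_resize(img: np.ndarray, target: int,
                         boxes: list[NormalizedBox] | None = None,
                         source_id: str = "") -> LabeledImage:
    """Min-max intensity normalization + aspect-preserving letterbox.

    A constant image maps to 0.5 everywhere; padding uses grey 114/255.
    Box coordinates are remapped into the letterboxed frame.
    """
    img = _to_chw(img)
    if img.size == 0:
        raise ValueError("empty image")
    lo, hi = float(img.min()), float(img.max())
    img = np.full_like(img, 0.5) if hi - lo < 1e-12 else (img - lo) / (hi - lo)

    _, h, w = img.shape
    r = min(target / h, target / w)
    nh, nw = max(round(h * r), 1), max(round(w * r), 1)
    if (nh, nw) != (h, w):
        hwc = np.moveaxis(img, 0, -1)
        hwc = sk_resize(hwc, (nh, nw), order=1, preserve_range=True,
                        anti_aliasing=nh < h).astype(np.float32)
        img = np.moveaxis(hwc, -1, 0)
    top = (target - nh) // 2
    left = (target - nw) // 2
    canvas = np.full((3, target, target), PAD_VALUE, dtype=np.float32)
    canvas[:, top:top + nh, left:left + nw] = img

    out_boxes = []
    for b in boxes or []:
        xc = (b.xc * nw + left) / target
        yc = (b.yc * nh + top) / target
        nb = clip_box(xc - b.w * nw / (2 * target), yc - b.h * nh / (2 * target),
                      xc + b.w * nw / (2 * target), yc + b.h * nh / (2 * target),
                      b.class_id)
        if nb is not None:
            out_boxes.append(nb)
    return LabeledImage(canvas, out_boxes, source_id)


# -------------------------------------------------------------- augmentation
def hflip(sample: LabeledImage) -> LabeledImage:
    img = sample.image[:, :, ::-1].copy()
    boxes = [replace(b, xc=1.0 - b.xc) for b in sample.boxes]
    return LabeledImage(img, boxes, sample.source_id)


def rotate(sample: LabeledImage, angle_deg: float) -> LabeledImage:
    """Rotate about the image center (border fill 114/255).

    Each box becomes the axis-aligned hull of its four rotated corners;
    boxes falling below the clipped-area threshold are dropped.
    """
    from scipy import ndimage

    if angle_deg == 0.0:
        return LabeledImage(sample.image.copy(), list(sample.boxes),
                            sample.source_id)
    img = ndimage.rotate(sample.image, angle_deg, axes=(2, 1),
                         reshape=False, order=1, mode="constant",
                         cval=PAD_VALUE).astype(np.float32)
    np.clip(img, 0.0, 1.0, out=img)
    _, h, w = img.shape
    th = math.radians(angle_deg)
    cos_t, sin_t = math.cos(th), math.sin(th)
    boxes = []
    for b in sample.boxes:
        x1, y1, x2, y2 = b.corners()
        pts = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]]) - 0.5
        # image-array rotation: col' = c*cos - r*sin ; row' = c*sin + r*cos
        xs = pts[:, 0] * cos_t - pts[:, 1] * sin_t + 0.5
        ys = pts[:, 0] * sin_t + pts[:, 1] * cos_t + 0.5
        nb = clip_box(xs.min(), ys.min(), xs.max(), ys.max(), b.class_id,
                      orig_area=b.w * b.h)
        if nb is not None and nb.w * w >= MIN_BOX_SIDE_PX and nb.h * h >= MIN_BOX_SIDE_PX:
            boxes.append(nb)
    return LabeledImage(img, boxes, sample.source_id)


def hsv_jitter(sample: LabeledImage, gains=(0.015, 0.015, 0.015),
               rng: np.random.Generator | None = None) -> LabeledImage:
    """Multiplicative HSV jitter; hue wraps, saturation/value clip."""
    rng = rng or np.random.default_rng(0)
    u = rng.uniform(-1.0, 1.0, size=3)
    hwc = np.moveaxis(sample.image, 0, -1)
    hsv = skcolor.rgb2hsv(hwc)
    hsv[..., 0] = np.mod(hsv[..., 0] * (1.0 + u[0] * gains[0]), 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + u[1] * gains[1]), 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + u[2] * gains[2]), 0.0, 1.0)
    rgb = skcolor.hsv2rgb(hsv).astype(np.float32)
    return LabeledImage(np.moveaxis(rgb, -1, 0).copy(), list(sample.boxes),
                        sample.source_id)


def mosaic(samples: list[LabeledImage], out_size: int,
           rng: np.random.Generator) -> LabeledImage:
    """2x2 collage of four same-size samples around a random center.

    The four tiles are laid out on a ``2*out_size`` canvas around a center
    drawn uniformly in the [0.25, 0.75] band, then the canvas is rescaled
    to ``out_size`` (so with the center pinned to the exact middle, a
    centered box in each tile lands at the four quadrant centers).
    """
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 samples")
    s = out_size
    canvas = np.full((3, 2 * s, 2 * s), PAD_VALUE, dtype=np.float32)
    cx = int(rng.uniform(0.25, 0.75) * 2 * s)
    cy = int(rng.uniform(0.25, 0.75) * 2 * s)
    boxes: list[NormalizedBox] = []
    for i, sm in enumerate(samples):
        img = sm.image
        if img.shape[1] != s or img.shape[2] != s:
            raise ValueError("mosaic inputs must be letterboxed to out_size")
        if i == 0:    # top-left tile, anchored at (cx, cy)
            x1a, y1a = max(cx - s, 0), max(cy - s, 0)
            x2a, y2a = cx, cy
        elif i == 1:  # top-right
            x1a, y1a = cx, max(cy - s, 0)
            x2a, y2a = min(cx + s, 2 * s), cy
        elif i == 2:  # bottom-left
            x1a, y1a = max(cx - s, 0), cy
            x2a, y2a = cx, min(cy + s, 2 * s)
        else:         # bottom-right
            x1a, y1a = cx, cy
            x2a, y2a = min(cx + s, 2 * s), min(cy + s, 2 * s)
        w_t, h_t = x2a - x1a, y2a - y1a
        if w_t <= 0 or h_t <= 0:
            continue
        # matching source window (tiles meet at the shared center corner)
        x1b = s - w_t if i in (0, 2) else 0
        y1b = s - h_t if i in (0, 1) else 0
        canvas[:, y1a:y1a + h_t, x1a:x1a + w_t] = \
            img[:, y1b:y1b + h_t, x1b:x1b + w_t]
        for b in sample_boxes_px(sm, s):
            bx1 = (b[0] - x1b + x1a) / (2 * s)
            by1 = (b[1] - y1b + y1a) / (2 * s)
            bx2 = (b[2] - x1b + x1a) / (2 * s)
            by2 = (b[3] - y1b + y1a) / (2 * s)
            # clip to the pasted window before the unit square
            wx1, wy1 = x1a / (2 * s), y1a / (2 * s)
            wx2, wy2 = x2a / (2 * s), y2a / (2 * s)
            nb = clip_box(max(bx1, wx1), max(by1, wy1),
                          min(bx2, wx2), min(by2, wy2), int(b[4]),
                          orig_area=(b[2] - b[0]) * (b[3] - b[1]) / (2 * s) ** 2)
            if nb is not None and nb.w * 2 * s >= MIN_BOX_SIDE_PX \
                    and nb.h * 2 * s >= MIN_BOX_SIDE_PX:
                boxes.append(nb)
    hwc = np.moveaxis(canvas, 0, -1)
    small = sk_resize(hwc, (s, s), order=1, preserve_range=True,
                      anti_aliasing=True).astype(np.float32)
    return LabeledImage(np.moveaxis(small, -1, 0).copy(), boxes, "mosaic")


def sample_boxes_px(sample: LabeledImage, size: int) -> np.ndarray:
    """Boxes as pixel corner rows (x1, y1, x2, y2, class)."""
    rows = [(b.xc * size - b.w * size / 2, b.yc * size - b.h * size / 2,
             b.xc * size + b.w * size / 2, b.yc * size + b.h * size / 2,
             b.class_id) for b in sample.boxes]
    return np.array(rows, dtype=np.float32).reshape(-1, 5)


def mixup(a: LabeledImage, b: LabeledImage, alpha: float = 0.2,
          rng: np.random.Generator | None = None,
          lam: float | None = None) -> LabeledImage:
    """Convex blend of two samples with label union (lambda ~ Beta(a, a))."""
    rng = rng or np.random.default_rng(0)
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    img = lam * a.image + (1.0 - lam) * b.image
    return LabeledImage(img.astype(np.float32), list(a.boxes) + list(b.boxes),
                        f"mixup({a.source_id},{b.source_id})")


# -------------------------------------------------------------------- splits
def _largest_remainder(counts: list[int], frac: float) -> list[int]:
    exact = [c * frac for c in counts]
    floors = [int(math.floor(e)) for e in exact]
    total = int(round(sum(exact)))
    leftover = total - sum(floors)
    order = sorted(range(len(counts)), key=lambda i: exact[i] - floors[i],
                   reverse=True)
    out = list(floors)
    for i in order[:leftover]:
        out[i] += 1
    return out


def stratified_split(items: list, classes: list[int], train_frac: float = 0.8,
                     seed: int = 0) -> tuple[list, list]:
    """Per-class split with largest-remainder rounding of the train sizes."""
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, c in enumerate(classes):
        by_class.setdefault(c, []).append(i)
    keys = sorted(by_class)
    n_train = _largest_remainder([len(by_class[k]) for k in keys], train_frac)
    train_idx, val_idx = [], []
    for k, nt in zip(keys, n_train):
        idx = np.array(by_class[k])
        rng.shuffle(idx)
        train_idx.extend(idx[:nt].tolist())
        val_idx.extend(idx[nt:].tolist())
    return ([items[i] for i in sorted(train_idx)],
            [items[i] for i in sorted(val_idx)])


def kfold_split(items: list, classes: list[int], k: int = 5,
                seed: int = 0) -> list[tuple[list, list]]:
    """Stratified k folds: per-class sizes differ by at most one."""
    if k < 2:
        raise ValueError("k-fold needs k >= 2")
    rng = np.random.default_rng(seed)
    fold_idx: list[list[int]] = [[] for _ in range(k)]
    by_class: dict[int, list[int]] = {}
    for i, c in enumerate(classes):
        by_class.setdefault(c, []).append(i)
    for c in sorted(by_class):
        idx = np.array(by_class[c])
        rng.shuffle(idx)
        for f in range(k):
            fold_idx[f].extend(idx[f::k].tolist())
    folds = []
    for f in range(k):
        val = sorted(fold_idx[f])
        train = sorted(i for g in range(k) if g != f for i in fold_idx[g])
        folds.append(([items[i] for i in train], [items[i] for i in val]))
    return folds


# ------------------------------------------------------------------- dataset
@dataclass
class YoloDataset:
    """Directory-backed dataset: images/{split}/*.png + labels/{split}/*.txt."""
    root: Path
    split: str
    names: list[str]
    items: list[tuple[Path, Path]] = field(default_factory=list)

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def open(cls, root, split: str = "train") -> "YoloDataset":
        root = Path(root)
        with open(root / "dataset.yaml") as f:
            meta = yaml.safe_load(f)
        names = meta["names"]
        img_dir = root / "images" / split
        lbl_dir = root / "labels" / split
        items = []
        for p in sorted(img_dir.glob("*")):
            if p.suffix.lower() in (".png", ".jpg", ".jpeg"):
                items.append((p, lbl_dir / (p.stem + ".txt")))
        if not items:
            raise FileNotFoundError(f"no images under {img_dir}")
        return cls(root, split, names, items)

    def load(self, i: int, img_size: int) -> LabeledImage:
        img_path, lbl_path = self.items[i]
        img = np.asarray(Image.open(img_path).convert("RGB"), dtype=np.float32) / 255.0
        boxes = read_yolo_labels(lbl_path, self.num_classes) if lbl_path.exists() else []
        return normalize_and_resize(img, img_size, boxes, img_path.stem)

    def class_of(self, i: int) -> int:
        _, lbl = self.items[i]
        boxes = read_yolo_labels(lbl) if lbl.exists() else []
        return boxes[0].class_id if boxes else -1


@dataclass
class AugmentConfig:
    flip_p: float = 0.5
    rotate_deg: float = 10.0
    hsv_gains: tuple = (0.015, 0.015, 0.015)
    mosaic_p: float = 0.5
    mixup_p: float = 0.1
    mixup_alpha: float = 0.2


def augmented_sample(ds: YoloDataset, i: int, img_size: int,
                     rng: np.random.Generator,
                     aug: AugmentConfig | None = None) -> LabeledImage:
    """One augmented training sample (mosaic/mixup draw extra images)."""
    aug = aug or AugmentConfig()
    if rng.random() < aug.mosaic_p and len(ds) >= 4:
        others = rng.integers(0, len(ds), size=3)
        parts = [ds.load(j, img_size) for j in (i, *others)]
        s = mosaic(parts, img_size, rng)
        if rng.random() < aug.mixup_p:
            j = int(rng.integers(0, len(ds)))
            other = ds.load(j, img_size)
            s = mixup(s, other, aug.mixup_alpha, rng)
    else:
        s = ds.load(i, img_size)
    if rng.random() < aug.flip_p:
        s = hflip(s)
    ang = float(rng.uniform(-aug.rotate_deg, aug.rotate_deg))
    s = rotate(s, ang)
    s = hsv_jitter(s, aug.hsv_gains, rng)
    return s
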