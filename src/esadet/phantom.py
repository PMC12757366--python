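"""Synthetic brain-MRI phantom corpus with exact bounding-box ground truth.

The generator emulates the *structure* of the Figshare T1-weighted
contrast-enhanced corpus — 3,064 single-lesion slices over three classes
(glioma 1,426 / meningioma 708 / pituitary 930) from 233 subjects at
512x512 — with an invented, purely synthetic appearance model:

* background: a bright elliptical "skull" ring around smooth low-frequency
  brain texture, near-black exterior;
* glioma: large irregular low-contrast blob with feathered margins;
* meningioma: medium rounded blob with a bright rim;
* pituitary: small bright compact blob near the slice center.

Every sample carries the binary lesion mask and the tight box derived from
it, so labels are correct by construction.  This is not a physical MRI
simulation (no k-space, bias field or sequence physics); it exists so the
detection pipeline is exercisable and testable without patient data.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage.transform import resize as sk_resize

from .data import CLASS_NAMES, NormalizedBox, write_yolo_labels

FIGSHARE_COUNTS = {0: 1426, 1: 708, 2: 930}   # glioma, meningioma, pituitary
FIGSHARE_SUBJECTS = 233


@dataclass
class LesionStyle:
    """Geometry/appearance ranges of one class (fractions of canvas side)."""
    diameter: tuple[float, float]
    contrast: tuple[float, float]
    irregularity: float          # radial perturbation amplitude
    feather: float               # edge blur sigma as canvas fraction
    rim: float = 0.0             # extra rim brightness (meningioma)
    central: bool = False        # constrain near canvas center (pituitary)


DEFAULT_STYLES = {
    0: LesionStyle(diameter=(0.10, 0.20), contrast=(0.08, 0.15),
                   irregularity=0.30, feather=0.020),
    1: LesionStyle(diameter=(0.06, 0.12), contrast=(0.18, 0.28),
                   irregularity=0.08, feather=0.008, rim=0.22),
    2: LesionStyle(diameter=(0.03, 0.08), contrast=(0.35, 0.50),
                   irregularity=0.05, feather=0.004, central=True),
}


@dataclass
class PhantomSpec:
    canvas: int = 512
    counts: dict[int, int] = field(default_factory=lambda: dict(FIGSHARE_COUNTS))
    subjects: int = FIGSHARE_SUBJECTS
    styles: dict[int, LesionStyle] = field(default_factory=lambda: dict(DEFAULT_STYLES))
    interior_range: tuple[float, float] = (0.30, 0.60)
    seed: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("class counts must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PhantomSample:
    image: np.ndarray        # [3, H, W] float32 in [0, 1]
    mask: np.ndarray         # [H, W] bool
    box: NormalizedBox
    class_id: int
    subject_id: int


# ------------------------------------------------------------------ drawing
def _value_noise(canvas: int, rng: np.random.Generator,
                 octaves=(4, 8, 16)) -> np.ndarray:
    """Multi-octave smooth noise in [0, 1]."""
    acc = np.zeros((canvas, canvas), dtype=np.float32)
    weight = 1.0
    total = 0.0
    for g in octaves:
        grid = rng.random((g, g)).astype(np.float32)
        acc += weight * sk_resize(grid, (canvas, canvas), order=3,
                                  preserve_range=True).astype(np.float32)
        total += weight
        weight *= 0.5
    acc /= total
    lo, hi = acc.min(), acc.max()
    return (acc - lo) / (hi - lo + 1e-9)


def render_background(canvas: int, rng: np.random.Generator,
                      interior_range=(0.30, 0.60)
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale slice background; returns (image [H,W], brain mask)."""
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(np.float32)
    cx = canvas * (0.5 + rng.uniform(-0.02, 0.02))
    cy = canvas * (0.5 + rng.uniform(-0.02, 0.02))
    ax = canvas * rng.uniform(0.38, 0.44)
    ay = canvas * rng.uniform(0.42, 0.47)
    d = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    brain = d < 1.0
    ring = (d >= 1.0) & (d < (1.0 + 0.08) ** 2)
    lo, hi = interior_range
    tex = lo + (hi - lo) * _value_noise(canvas, rng)
    img = np.full((canvas, canvas), 0.02, dtype=np.float32)
    img += 0.02 * rng.random((canvas, canvas)).astype(np.float32)
    img[brain] = tex[brain]
    img[ring] = rng.uniform(0.75, 0.88)
    return np.clip(img, 0.0, 1.0), brain


def render_lesion(class_id: int, spec: PhantomSpec, rng: np.random.Generator,
                  center: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Lesion (mask, additive intensity patch) on the spec's canvas."""
    from scipy.ndimage import gaussian_filter

    style = spec.styles[class_id]
    n = spec.canvas
    diam = rng.uniform(*style.diameter) * n
    r0 = diam / 2.0
    if center is None:
        if style.central:
            cx = n * (0.5 + rng.uniform(-0.10, 0.10))
            cy = n * (0.5 + rng.uniform(-0.10, 0.10))
        else:
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.22) * n
            cx, cy = n / 2 + rad * math.cos(ang), n / 2 + rad * math.sin(ang)
    else:
        cx, cy = center
    ecc = rng.uniform(0.75, 1.0)          # ellipse axis ratio
    theta0 = rng.uniform(0, 2 * math.pi)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta0), math.sin(theta0)
    u = dx * ct + dy * st
    v = (-dx * st + dy * ct) / ecc
    rad = np.hypot(u, v)
    ang = np.arctan2(v, u)
    # low-order Fourier perturbation of the radius
    pert = np.zeros_like(ang)
    for k in range(2, 6):
        pert += rng.uniform(-1, 1) * np.cos(k * ang + rng.uniform(0, 2 * math.pi))
    pert *= style.irregularity / 3.0
    mask = rad < r0 * (1.0 + pert)
    if not mask.any():                    # degenerate draw: fall back to disc
        mask = rad < max(r0, 1.5)
    contrast = rng.uniform(*style.contrast)
    sigma = max(style.feather * n, 0.5)
    soft = gaussian_filter(mask.astype(np.float32), sigma)
    patch = contrast * soft
    if style.rim > 0:
        band = mask & (rad > 0.72 * r0)
        rim = gaussian_filter(band.astype(np.float32), sigma)
        patch += style.rim * rim
    return mask, patch.astype(np.float32)


def mask_to_bbox(mask: np.ndarray, class_id: int = 0) -> NormalizedBox:
    """Tight axis-aligned box over nonzero pixels, normalized by canvas."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if len(rows) == 0:
        raise ValueError("empty mask has no bounding box")
    h, w = mask.shape
    r1, r2 = rows[0], rows[-1] + 1
    c1, c2 = cols[0], cols[-1] + 1
    return NormalizedBox(xc=(c1 + c2) / (2 * w), yc=(r1 + r2) / (2 * h),
                         w=(c2 - c1) / w, h=(r2 - r1) / h, class_id=class_id)


def generate_sample(class_id: int, spec: PhantomSpec,
                    rng: np.random.Generator,
                    subject_id: int = 0) -> PhantomSample:
    bg, _ = render_background(spec.canvas, rng, spec.interior_range)
    mask, patch = render_lesion(class_id, spec, rng)
    img = np.clip(bg + patch, 0.0, 1.0)
    box = mask_to_bbox(mask, class_id)
    return PhantomSample(np.stack([img] * 3), mask, box, class_id, subject_id)


# ------------------------------------------------------------------- corpus
def _save_png(image: np.ndarray, path: Path) -> None:
    arr = (np.moveaxis(image, 0, -1) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(arr).save(path)


def generate_corpus(spec: PhantomSpec, out_dir, train_frac: float = 0.8,
                    write_masks: bool = False,
                    progress: bool = False) -> list[dict]:
    """Write the full corpus (images, labels, dataset YAML, manifest).

    Images are assigned round-robin to synthetic subject ids and split
    stratified-by-class into train/val.  Returns the manifest: one dict per
    image with file, class, subject and split.  Fixed seed => identical
    corpus bit for bit.
    """
    from .data import stratified_split

    out = Path(out_dir)
    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    if write_masks:
        (out / "masks").mkdir(exist_ok=True)

    plan = []                      # (name, class_id, subject)
    subject = 0
    idx = 0
    for cid in sorted(spec.counts):
        for _ in range(spec.counts[cid]):
            plan.append((f"{CLASS_NAMES[cid]}_{idx:05d}", cid, subject))
            subject = (subject + 1) % spec.subjects
            idx += 1
    train_items, val_items = stratified_split(
        plan, [p[1] for p in plan], train_frac, seed=spec.seed)
    split_of = {p[0]: "train" for p in train_items}
    split_of.update({p[0]: "val" for p in val_items})

    rng = np.random.default_rng(spec.seed)
    manifest = []
    iterator = plan
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(plan, desc="phantom corpus")
        except ImportError:
            pass
    for name, cid, subj in iterator:
        sample = generate_sample(cid, spec, rng, subj)
        split = split_of[name]
        img_path = out / "images" / split / f"{name}.png"
        _save_png(sample.image, img_path)
        write_yolo_labels([sample.box], out / "labels" / split / f"{name}.txt")
        if write_masks:
            Image.fromarray((sample.mask * 255).astype(np.uint8)).save(
                out / "masks" / f"{name}.png")
        manifest.append({"file": str(img_path.relative_to(out)),
                         "class": CLASS_NAMES[cid], "class_id": cid,
                         "subject": subj, "split": split})

    with open(out / "dataset.yaml", "w") as f:
        yaml.safe_dump({"path": str(out), "train": "images/train",
                        "val": "images/val", "names": CLASS_NAMES}, f)
    with open(out / "manifest.csv", "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=["file", "class", "class_id",
                                          "subject", "split"])
        w.writeheader()
        w.writerows(manifest)
    return manifest


def manifest_hash(manifest: list[dict]) -> str:
    h = hashlib.sha256()
    for row in manifest:
        h.update(repr(sorted(row.items())).encode())
    return h.hexdigest()


def tiny_benchmark(seed: int, out_dir, canvas: int = 160,
                   n_train: int = 120, n_val: int = 30):
    """Small balanced corpus (default 120 train + 30 val at 160x160).

    Returns the (train, val) :class:`~esadet.data.YoloDataset` pair.
    """
    from .data import YoloDataset

    per_class = {c: (n_train + n_val) // 3 for c in range(3)}
    rem = (n_train + n_val) - sum(per_class.values())
    for c in range(rem):
        per_class[c] += 1
    spec = PhantomSpec(canvas=canvas, counts=per_class,
                       subjects=max((n_train + n_val) // 5, 1), seed=seed)
    generate_corpus(spec, out_dir, train_frac=n_train / (n_train + n_val))
    return (YoloDataset.open(out_dir, "train"), YoloDataset.open(out_dir, "val"))
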