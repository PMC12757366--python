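"""End-to-end training: AdamW + cosine annealing, early stopping on
validation mAP@0.5, best-checkpoint selection, placement ablation and
stratified five-fold cross-validation.

The learning-rate schedule is ``eta_t = eta_0 * (1 + cos(t*pi/E)) / 2``
(epoch-indexed), optionally preceded by a short linear warmup.  The best
model is the epoch with the highest validation mAP@0.5; training halts
early once that metric has not improved for ``patience`` epochs.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .data import AugmentConfig, YoloDataset, augmented_sample
from .losses import LossWeights, build_targets, composite_loss
from .metrics import Detection, EvalResult, GroundTruth, evaluate, nms as run_nms
from .model import (Detector, DetectorConfig, build_detector,
                    decode_predictions)


def cosine_lr(t: int, total_epochs: int, lr0: float) -> float:
    """Cosine-annealed learning rate at epoch ``t`` of ``total_epochs``."""
    if not 0 <= t <= total_epochs or total_epochs < 1:
        raise ValueError(f"epoch {t} outside [0, {total_epochs}]")
    return lr0 * 0.5 * (1.0 + math.cos(t * math.pi / total_epochs))


def fit_anchors(ds: YoloDataset, img_size: int, seed: int = 0) -> tuple:
    """Fit 9 anchor priors to the dataset's box sizes (k-means on w, h).

    The standard recipe re-estimates anchors per dataset; this is the same
    idea at desk scale: cluster the letterboxed label extents in pixels and
    hand three ascending-area anchors to each detection scale.
    """
    whs = []
    for i in range(len(ds)):
        for b in ds.load(i, img_size).boxes:
            whs.append([b.w * img_size, b.h * img_size])
    wh = np.maximum(np.array(whs, dtype=np.float64), 2.0)
    from scipy.cluster.vq import kmeans2
    cents, _ = kmeans2(wh, 9, minit="++", seed=seed)
    cents = cents[np.argsort(cents.prod(axis=1))]
    cents = np.maximum(cents, 1.0)
    return tuple(tuple(tuple(float(v) for v in c) for c in cents[3 * s:3 * s + 3])
                 for s in range(3))


@dataclass
class TrainConfig:
    epochs: int = 150
    batch: int = 16
    lr0: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    label_smoothing: float = 0.1
    patience: int = 30
    conf_threshold: float = 0.25   # deployment/prediction threshold
    eval_conf: float = 0.001       # PR-curve floor for mAP evaluation
    nms_iou: float = 0.45
    seed: int = 0
    img_size: int = 640
    loss_weights: LossWeights = field(default_factory=LossWeights)
    amp: bool = False             # accepted and recorded; pass-through flag
    warmup_epochs: int = 3
    accumulate: int | None = None  # None -> max(1, round(64 / batch))
    eval_interval: int = 1
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.lr0 <= 0 or self.patience < 1:
            raise ValueError("epochs >= 1, lr0 > 0 and patience >= 1 required")

    def effective_accumulate(self) -> int:
        return self.accumulate if self.accumulate else max(1, round(64 / self.batch))

    def epoch_lr(self, t: int) -> float:
        if self.warmup_epochs and t < self.warmup_epochs:
            return self.lr0 * (t + 1) / self.warmup_epochs
        return cosine_lr(t, self.epochs, self.lr0)


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_map50: float = 0.0

    def append(self, row: dict) -> None:
        self.epochs.append(row)

    def save_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"best_epoch": self.best_epoch,
                       "best_map50": self.best_map50,
                       "epochs": self.epochs}, f, indent=2)


def _param_groups(model: Detector, weight_decay: float):
    decay, no_decay = [], []
    for name, p in model.named_parameters():
        (decay if p.data.ndim == 4 else no_decay).append(p)
    return [{"params": decay, "weight_decay": weight_decay},
            {"params": no_decay, "weight_decay": 0.0}]


def _batch_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    rows = []
    for bi, s in enumerate(samples):
        for b in s.boxes:
            rows.append([bi, b.class_id, b.xc, b.yc, b.w, b.h])
    targets = np.array(rows, dtype=np.float32).reshape(-1, 6)
    return imgs, targets


def evaluate_model(model: Detector, ds: YoloDataset, cfg: TrainConfig,
                   batch: int = 8) -> EvalResult:
    """Letterbox the split, run inference + NMS, score against the labels."""
    mcfg = model.cfg
    model.eval()
    dets_by_image: dict[str, list[Detection]] = {}
    gts_by_image: dict[str, list[GroundTruth]] = {}
    size = cfg.img_size
    for start in range(0, len(ds), batch):
        idxs = range(start, min(start + batch, len(ds)))
        samples = [ds.load(i, size) for i in idxs]
        imgs = np.stack([s.image for s in samples])
        with nn.no_grad():
            outs = model.forward(imgs)
        raws = [o.data for o in outs]
        for k, s in enumerate(samples):
            per_img = [r[k] for r in raws]
            run_cfg = mcfg if mcfg.img_size == size else replace(mcfg, img_size=size)
            dets = decode_predictions(per_img, run_cfg, cfg.eval_conf,
                                      image_id=s.source_id)
            dets_by_image[s.source_id] = run_nms(dets, cfg.eval_conf,
                                                 cfg.nms_iou)
            gts_by_image[s.source_id] = [
                GroundTruth(b.corners(size, size), b.class_id, s.source_id)
                for b in s.boxes]
    return evaluate(dets_by_image, gts_by_image, ds.num_classes, ds.names,
                    cfg.eval_conf, cfg.nms_iou, apply_nms=False)


def train(model: Detector, train_set: YoloDataset, val_set: YoloDataset,
          cfg: TrainConfig, out_dir=None, log=print
          ) -> tuple[TrainHistory, dict[str, np.ndarray]]:
    """Train and return (history, best state_dict); checkpoints land in
    ``out_dir`` when given."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if train_set.num_classes != model.cfg.num_classes:
        raise ValueError(
            f"dataset has {train_set.num_classes} classes, model head expects "
            f"{model.cfg.num_classes}")
    out = Path(out_dir) if out_dir else None
    run_log = None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        cfg_text = model.cfg.to_yaml()
        (out / "config.yaml").write_text(cfg_text)
        import hashlib
        cfg_hash = hashlib.sha256(
            (cfg_text + repr(cfg)).encode()).hexdigest()[:16]
        run_log = open(out / "run.log", "w")
        run_log.write(f"seed={cfg.seed} config_hash={cfg_hash}\n")

    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    opt = nn.AdamW(_param_groups(model, cfg.weight_decay),
                   lr=cfg.lr0, betas=cfg.betas)
    accumulate = cfg.effective_accumulate()
    grids = [(cfg.img_size // s, cfg.img_size // s) for s in model.cfg.strides]
    best_state = model.state_dict()
    epochs_since_best = 0

    for epoch in range(cfg.epochs):
        t0 = time.time()
        opt.lr = cfg.epoch_lr(epoch)
        model.train()
        order = rng.permutation(len(train_set))
        sums = {"cls": 0.0, "obj": 0.0, "loc": 0.0, "total": 0.0}
        n_batches = 0
        opt.zero_grad()
        for bstart in range(0, len(order), cfg.batch):
            idxs = order[bstart:bstart + cfg.batch]
            samples = [augmented_sample(train_set, int(i), cfg.img_size, rng,
                                        cfg.augment) for i in idxs]
            imgs, targets = _batch_arrays(samples)
            outs = model.forward(imgs)
            assignment = build_targets(targets, model.cfg, grids)
            loss, parts = composite_loss(outs, assignment, cfg.loss_weights,
                                         cfg.label_smoothing,
                                         model.cfg.num_classes)
            loss.backward()
            for k in sums:
                sums[k] += parts[k]
            n_batches += 1
            if n_batches % accumulate == 0:
                opt.step()
                opt.zero_grad()
        if n_batches % accumulate:
            opt.step()
            opt.zero_grad()

        row = {"epoch": epoch, "lr": opt.lr,
               **{k: v / max(n_batches, 1) for k, v in sums.items()}}
        if (epoch + 1) % cfg.eval_interval == 0 or epoch == cfg.epochs - 1:
            res = evaluate_model(model, val_set, cfg)
            row.update(map50=res.map50, map50_95=res.map50_95,
                       precision=res.precision, recall=res.recall)
            if res.map50 > history.best_map50 or history.best_epoch < 0:
                history.best_map50 = res.map50
                history.best_epoch = epoch
                best_state = model.state_dict()
                epochs_since_best = 0
                if out:
                    model.save(out / "best.ckpt")
            else:
                epochs_since_best += cfg.eval_interval
        row["seconds"] = round(time.time() - t0, 2)
        history.append(row)
        if run_log:
            run_log.write(" ".join(f"{k}={v}" for k, v in row.items()) + "\n")
            run_log.flush()
        if log:
            log(f"epoch {epoch:3d} lr={opt.lr:.2e} loss={row['total']:.3f} "
                f"map50={row.get('map50', float('nan')):.3f}")
        if epochs_since_best >= cfg.patience:
            break

    model.load_state_dict(best_state)
    if out:
        history.save_json(out / "history.json")
    if run_log:
        run_log.close()
    return history, best_state


def ablate_placement(train_set: YoloDataset, val_set: YoloDataset,
                     base_cfg: DetectorConfig, tcfg: TrainConfig,
                     seeds: tuple[int, ...] = (0,), out_dir=None,
                     log=print) -> list[dict]:
    """Train {none, before_sppf, after_sppf} under identical seeds/config."""
    rows = []
    for placement in ("none", "before_sppf", "after_sppf"):
        per_seed = []
        for seed in seeds:
            nn.seed_all(seed)
            model = build_detector(replace(base_cfg, placement=placement))
            run_cfg = replace(tcfg, seed=seed)
            sub = Path(out_dir) / f"{placement}_s{seed}" if out_dir else None
            hist, _ = train(model, train_set, val_set, run_cfg, sub, log=None)
            res = evaluate_model(model, val_set, run_cfg)
            per_seed.append(res)
            if log:
                log(f"{placement} seed={seed}: mAP@0.5={res.map50:.3f}")
        rows.append({
            "variant": placement,
            "map50": float(np.mean([r.map50 for r in per_seed])),
            "map50_sd": float(np.std([r.map50 for r in per_seed], ddof=1))
            if len(per_seed) > 1 else 0.0,
            "precision": float(np.mean([r.precision for r in per_seed])),
            "recall": float(np.mean([r.recall for r in per_seed])),
            "seeds": list(seeds),
        })
    return rows


def crossvalidate(ds: YoloDataset, base_cfg: DetectorConfig, tcfg: TrainConfig,
                  k: int = 5, out_dir=None, log=print):
    """Stratified k-fold train/evaluate; returns (per-fold, mean +/- SD)."""
    from .data import kfold_split
    from .metrics import summarize_folds

    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    classes = [ds.class_of(i) for i in range(len(ds))]
    folds = kfold_split(ds.items, classes, k, tcfg.seed)
    per_fold = []
    for f, (train_items, val_items) in enumerate(folds):
        nn.seed_all(tcfg.seed + f)
        model = build_detector(base_cfg)
        tr = replace(ds, items=train_items)
        va = replace(ds, items=val_items)
        sub = Path(out_dir) / f"fold{f}" if out_dir else None
        train(model, tr, va, replace(tcfg, seed=tcfg.seed + f), sub, log=None)
        res = evaluate_model(model, va, tcfg)
        per_fold.append({"map50": res.map50, "map50_95": res.map50_95,
                         "precision": res.precision, "recall": res.recall})
        if log:
            log(f"fold {f}: mAP@0.5={res.map50:.3f}")
    return per_fold, summarize_folds(per_fold)


def predict(model: Detector, image_paths, tcfg: TrainConfig | None = None,
            overlay_dir=None) -> dict[str, list[dict]]:
    """Decode + NMS on arbitrary images; optional rendered overlays."""
    from PIL import Image as PILImage
    from .data import normalize_and_resize

    tcfg = tcfg or TrainConfig(img_size=model.cfg.img_size)
    model.eval()
    results: dict[str, list[dict]] = {}
    for p in image_paths:
        p = Path(p)
        arr = np.asarray(PILImage.open(p).convert("RGB"), dtype=np.float32) / 255.0
        sample = normalize_and_resize(arr, tcfg.img_size, [], p.stem)
        with nn.no_grad():
            outs = model.forward(sample.image[None])
        run_cfg = (model.cfg if model.cfg.img_size == tcfg.img_size
                   else replace(model.cfg, img_size=tcfg.img_size))
        dets = decode_predictions([o.data[0] for o in outs], run_cfg,
                                  tcfg.conf_threshold, image_id=p.stem)
        dets = run_nms(dets, tcfg.conf_threshold, tcfg.nms_iou)
        results[p.stem] = [{"box": list(d.box), "score": d.score,
                            "class_id": d.class_id} for d in dets]
        if overlay_dir:
            _render_overlay(sample.image, dets, Path(overlay_dir) / f"{p.stem}.png")
    return results


def _render_overlay(image: np.ndarray, dets: list[Detection], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .data import CLASS_NAMES

    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.moveaxis(image, 0, -1))
    for d in dets:
        x1, y1, x2, y2 = d.box
        ax.add_patch(plt.Rectangle((x1, y1), x2 - x1, y2 - y1, fill=False,
                                   edgecolor="red", linewidth=1.5))
        name = CLASS_NAMES[d.class_id] if d.class_id < len(CLASS_NAMES) else d.class_id
        ax.text(x1, y1 - 2, f"{name} {d.score:.2f}", color="red", fontsize=7)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
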