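"""Detection evaluation: NMS, matching, average precision, mAP, confusion.

AP is the exact area under the monotone (enveloped) precision-recall curve,
integrated over every distinct recall point — not an 11- or 101-point
approximation.  mAP@0.5:0.95 averages AP over the ten IoU thresholds
0.50, 0.55, ..., 0.95.  Aggregate precision/recall are reported at the
score threshold maximizing F1 on the IoU-0.5 PR curve.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

IOU_RANGE = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass
class Detection:
    box: tuple[float, float, float, float]   # pixel x1, y1, x2, y2
    score: float
    class_id: int
    image_id: str = ""

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0,1]")


@dataclass
class GroundTruth:
    box: tuple[float, float, float, float]
    class_id: int
    image_id: str = ""


def iou(a, b) -> float:
    """Intersection over union of two (x1,y1,x2,y2) boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def _det_sort_key(d: Detection):
    # stable, deterministic: score desc then (image_id, coordinates)
    return (-d.score, d.image_id, d.box)


def nms(dets: list[Detection], conf: float = 0.25,
        iou_thr: float = 0.45) -> list[Detection]:
    """Greedy class-wise non-maximum suppression, output sorted by score."""
    dets = sorted((d for d in dets if d.score >= conf), key=_det_sort_key)
    kept: list[Detection] = []
    suppressed = [False] * len(dets)
    for i, d in enumerate(dets):
        if suppressed[i]:
            continue
        kept.append(d)
        for j in range(i + 1, len(dets)):
            if (not suppressed[j] and dets[j].class_id == d.class_id
                    and iou(d.box, dets[j].box) > iou_thr):
                suppressed[j] = True
    return kept


def match_detections(dets: list[Detection], gts: list[GroundTruth],
                     iou_thr: float = 0.5) -> tuple[list[bool], list[bool]]:
    """Greedy one-to-one matching in descending score order.

    Each detection claims the highest-IoU unmatched same-class ground truth
    (same image) with IoU >= threshold.  Returns per-detection TP flags (in
    the order of the score-sorted detections — sort first) and per-gt
    matched flags.
    """
    order = sorted(range(len(dets)), key=lambda i: _det_sort_key(dets[i]))
    tp = [False] * len(dets)
    matched = [False] * len(gts)
    for i in order:
        d = dets[i]
        best_iou, best_j = iou_thr, -1
        for j, g in enumerate(gts):
            if matched[j] or g.class_id != d.class_id or g.image_id != d.image_id:
                continue
            v = iou(d.box, g.box)
            if v >= best_iou and (best_j == -1 or v > best_iou):
                best_iou, best_j = v, j
        if best_j >= 0:
            tp[i] = True
            matched[best_j] = True
    return tp, matched


def average_precision(tp_flags: list[bool], scores: list[float],
                      n_gt: int) -> float:
    """Exact AP: cumulate in score order, envelope precision, integrate."""
    if n_gt == 0:
        return 0.0
    if not tp_flags:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    tp = np.asarray(tp_flags, dtype=np.float64)[order]
    fp = 1.0 - tp
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / (ctp + cfp)
    # monotone non-increasing precision envelope
    r = np.concatenate(([0.0], recall, [1.0]))
    p = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.where(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


@dataclass
class EvalResult:
    class_names: list[str]
    ap50: dict[int, float]
    ap50_95: dict[int, float]
    map50: float
    map50_95: float
    precision: float
    recall: float
    f1_threshold: float
    per_class_pr: dict[int, tuple[float, float]]
    pr_curves: dict[int, tuple[list[float], list[float]]] = field(default_factory=dict)
    confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "map50": self.map50, "map50_95": self.map50_95,
            "precision": self.precision, "recall": self.recall,
            "f1_threshold": self.f1_threshold,
            "per_class": {
                self.class_names[c] if c < len(self.class_names) else str(c): {
                    "ap50": self.ap50[c], "ap50_95": self.ap50_95[c],
                    "precision": self.per_class_pr[c][0],
                    "recall": self.per_class_pr[c][1],
                } for c in sorted(self.ap50)
            },
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d

    def save_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["class", "ap50", "ap50_95", "precision", "recall"])
            for c in sorted(self.ap50):
                name = self.class_names[c] if c < len(self.class_names) else str(c)
                w.writerow([name, self.ap50[c], self.ap50_95[c],
                            *self.per_class_pr[c]])
            w.writerow(["all", self.map50, self.map50_95,
                        self.precision, self.recall])


def evaluate(dets_by_image: dict[str, list[Detection]],
             gts_by_image: dict[str, list[GroundTruth]],
             num_classes: int,
             class_names: list[str] | None = None,
             conf: float = 0.25, nms_iou: float = 0.45,
             apply_nms: bool = True) -> EvalResult:
    """Full evaluation over a split: per-class AP at 0.5 and 0.5:0.95."""
    class_names = class_names or [str(c) for c in range(num_classes)]
    all_dets: list[Detection] = []
    for img, dets in dets_by_image.items():
        d = nms(dets, conf, nms_iou) if apply_nms else list(dets)
        for x in d:
            if x.image_id != img:
                x = Detection(x.box, x.score, x.class_id, img)
            all_dets.append(x)
    all_gts = [g if g.image_id == img else GroundTruth(g.box, g.class_id, img)
               for img, gs in gts_by_image.items() for g in gs]

    ap50, ap_all, per_class_pr, pr_curves = {}, {}, {}, {}
    f1_best = (0.0, conf)
    for c in range(num_classes):
        cd = sorted((d for d in all_dets if d.class_id == c), key=_det_sort_key)
        cg = [g for g in all_gts if g.class_id == c]
        n_gt = len(cg)
        if n_gt == 0 and not cd:
            continue
        aps = {}
        tp50 = None
        for thr in IOU_RANGE:
            tp, _ = match_detections(cd, cg, thr)
            aps[thr] = average_precision(tp, [d.score for d in cd], n_gt)
            if thr == 0.5:
                tp50 = tp
        ap50[c] = aps[0.5]
        ap_all[c] = float(np.mean(list(aps.values())))
        scores = np.array([d.score for d in cd])
        tps = np.cumsum(tp50) if cd else np.array([])
        if len(cd) and n_gt:
            prec = tps / np.arange(1, len(cd) + 1)
            rec = tps / n_gt
            pr_curves[c] = (rec.tolist(), prec.tolist())
        else:
            pr_curves[c] = ([], [])

    # aggregate operating point: max F1 over score thresholds (IoU 0.5)
    precision = recall = 0.0
    thr_star = conf
    cand = sorted({round(d.score, 4) for d in all_dets})
    best_f1 = -1.0
    for t in cand or [conf]:
        sel = [d for d in all_dets if d.score >= t]
        tp, matched = match_detections(sel, all_gts, 0.5)
        ntp = sum(tp)
        p = ntp / len(sel) if sel else 0.0
        r = ntp / len(all_gts) if all_gts else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1:
            best_f1, precision, recall, thr_star = f1, p, r, t

    for c in list(ap50):
        sel = [d for d in all_dets if d.class_id == c and d.score >= thr_star]
        cg = [g for g in all_gts if g.class_id == c]
        tp, _ = match_detections(sel, cg, 0.5)
        ntp = sum(tp)
        per_class_pr[c] = (ntp / len(sel) if sel else 0.0,
                           ntp / len(cg) if cg else 0.0)

    classes = sorted(ap50)
    map50 = float(np.mean([ap50[c] for c in classes])) if classes else 0.0
    map50_95 = float(np.mean([ap_all[c] for c in classes])) if classes else 0.0
    conf_mat = confusion_matrix(all_dets, all_gts, num_classes,
                                conf=conf, iou_thr=nms_iou, pre_nms=False)
    return EvalResult(class_names, ap50, ap_all, map50, map50_95,
                      precision, recall, thr_star, per_class_pr,
                      pr_curves, conf_mat)


def confusion_matrix(dets: list[Detection], gts: list[GroundTruth],
                     num_classes: int, conf: float = 0.25,
                     iou_thr: float = 0.45, pre_nms: bool = True
                     ) -> np.ndarray:
    """(C+1)x(C+1) counts; rows = predicted (+background), cols = true."""
    mat = np.zeros((num_classes + 1, num_classes + 1), dtype=np.int64)
    dets = [d for d in dets if d.score >= conf]
    if pre_nms:
        dets = nms(dets, conf, iou_thr)
    matched_gt = [False] * len(gts)
    matched_det = [False] * len(dets)
    order = sorted(range(len(dets)), key=lambda i: _det_sort_key(dets[i]))
    for i in order:
        d = dets[i]
        best_iou, best_j = iou_thr, -1
        for j, g in enumerate(gts):
            if matched_gt[j] or g.image_id != d.image_id:
                continue
            v = iou(d.box, g.box)
            if v >= best_iou and (best_j == -1 or v > best_iou):
                best_iou, best_j = v, j
        if best_j >= 0:
            mat[d.class_id, gts[best_j].class_id] += 1
            matched_gt[best_j] = True
            matched_det[i] = True
    for i, d in enumerate(dets):
        if not matched_det[i]:
            mat[d.class_id, num_classes] += 1
    for j, g in enumerate(gts):
        if not matched_gt[j]:
            mat[num_classes, g.class_id] += 1
    return mat


def summarize_folds(per_fold: list[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (n-1) of each metric across folds."""
    keys = per_fold[0].keys()
    out = {}
    for k in keys:
        vals = np.array([f[k] for f in per_fold], dtype=np.float64)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[k] = (float(vals.mean()), sd)
    return out


def plot_pr_curves(result: EvalResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c, (rec, prec) in result.pr_curves.items():
        name = result.class_names[c] if c < len(result.class_names) else str(c)
        ax.plot(rec, prec, label=f"{name} (AP@0.5={result.ap50[c]:.3f})")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
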