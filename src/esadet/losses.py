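"""Composite detection loss: classification + objectness + Complete-IoU.

    L_total = lambda_cls * L_cls + lambda_obj * L_obj + lambda_loc * L_CIoU

CIoU augments IoU with a normalized center-distance penalty and an
aspect-ratio consistency term:

    CIoU = IoU - rho^2(centers) / c_diag^2 - alpha_v * v
    v = (4 / pi^2) * (arctan(w_a/h_a) - arctan(w_b/h_b))^2
    alpha_v = v / ((1 - IoU) + v)

The training term is ``1 - CIoU``.  Target assignment follows the stock
anchor-ratio recipe: a label matches an anchor when
``max(w/wa, wa/w, h/ha, ha/h) < 4``, and each match also claims the two
nearest neighbor cells (offset threshold 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DetectorConfig
from .nn import Tensor, bce_with_logits, concat

EPS = 1e-7
ANCHOR_T = 4.0                  # anchor-ratio matching threshold
OBJ_BALANCE = (4.0, 1.0, 0.4)   # per-scale objectness weights (P3, P4, P5)


@dataclass
class LossWeights:
    lambda_cls: float = 0.5
    lambda_obj: float = 1.0
    lambda_loc: float = 0.05

    def __post_init__(self):
        if min(self.lambda_cls, self.lambda_obj, self.lambda_loc) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda_cls == self.lambda_obj == self.lambda_loc == 0:
            raise ValueError("at least one loss weight must be positive")


# --------------------------------------------------------------------- CIoU
def ciou(box_a, box_b) -> float:
    """Complete IoU of two corner boxes (x1, y1, x2, y2); value in (-1, 1]."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    wa, ha = ax2 - ax1, ay2 - ay1
    wb, hb = bx2 - bx1, by2 - by1
    if wa <= 0 or ha <= 0 or wb <= 0 or hb <= 0:
        raise ValueError("degenerate box passed to ciou")
    iw = max(min(ax2, bx2) - max(ax1, bx1), 0.0)
    ih = max(min(ay2, by2) - max(ay1, by1), 0.0)
    inter = iw * ih
    union = wa * ha + wb * hb - inter
    i = inter / (union + EPS)
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw ** 2 + ch ** 2 + EPS
    rho2 = ((ax1 + ax2 - bx1 - bx2) ** 2 + (ay1 + ay2 - by1 - by2) ** 2) / 4.0
    v = (4.0 / math.pi ** 2) * (math.atan(wa / ha) - math.atan(wb / hb)) ** 2
    alpha_v = v / ((1.0 - i) + v + EPS)
    return i - rho2 / c2 - alpha_v * v


def ciou_loss_t(pred_xywh: Tensor, target_xywh: np.ndarray) -> Tensor:
    """Differentiable CIoU of matched box pairs, center-size layout [n, 4].

    alpha_v is treated as a constant (evaluated at the current point), the
    standard practice for this loss.
    """
    px, py = pred_xywh[:, 0], pred_xywh[:, 1]
    pw = pred_xywh[:, 2].clamp_min(EPS)
    ph = pred_xywh[:, 3].clamp_min(EPS)
    t = np.asarray(target_xywh, dtype=np.float32)
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]

    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw * 0.5, tx + tw * 0.5
    ty1, ty2 = ty - th * 0.5, ty + th * 0.5

    iw = px2.minimum(Tensor(tx2)) - px1.maximum(Tensor(tx1))
    ih = py2.minimum(Tensor(ty2)) - py1.maximum(Tensor(ty1))
    inter = iw.clamp_min(0.0) * ih.clamp_min(0.0)
    union = pw * ph + Tensor(tw * th) - inter
    i = inter / (union + EPS)

    cw = px2.maximum(Tensor(tx2)) - px1.minimum(Tensor(tx1))
    ch = py2.maximum(Tensor(ty2)) - py1.minimum(Tensor(ty1))
    c2 = cw * cw + ch * ch + EPS
    rho2 = ((px - Tensor(tx)) ** 2 + (py - Tensor(ty)) ** 2)

    v = (pw / ph).arctan() - Tensor(np.arctan(tw / np.maximum(th, EPS)))
    v = v * v * (4.0 / math.pi ** 2)
    alpha_v = v.data / ((1.0 - i.data) + v.data + EPS)   # constant
    return i - rho2 / c2 - v * Tensor(alpha_v)


# ---------------------------------------------------------------- assignment
@dataclass
class TargetAssignment:
    """Positive samples of one batch, grouped per detection scale."""
    indices: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    tbox: list[np.ndarray]       # (dx, dy in cell, w, h in grid units)
    anchors: list[np.ndarray]    # matched anchor (w, h) in grid units
    tcls: list[np.ndarray]

    def num_positives(self) -> int:
        return sum(len(c) for c in self.tcls)


def build_targets(targets: np.ndarray, cfg: DetectorConfig,
                  grid_shapes: list[tuple[int, int]]) -> TargetAssignment:
    """Assign labels ``[n, 6] = (batch, cls, xc, yc, w, h)`` (normalized)
    to (scale, anchor, cell) positives, with neighbor-cell expansion."""
    na = 3
    g = 0.5
    off = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]],
                   dtype=np.float32) * g
    anchors_px = cfg.anchor_array()
    indices, tboxes, tanch, tclss = [], [], [], []
    n = len(targets)
    ai = np.tile(np.arange(na, dtype=np.float32)[:, None], (1, n))
    t0 = np.concatenate([np.tile(targets[None], (na, 1, 1)), ai[..., None]],
                        axis=2) if n else np.zeros((na, 0, 7), np.float32)

    for s, (stride, (gh, gw)) in enumerate(zip(cfg.strides, grid_shapes)):
        anc = anchors_px[s] / stride              # grid units
        gain = np.array([1, 1, gw, gh, gw, gh, 1], dtype=np.float32)
        t = t0 * gain
        if n:
            r = t[..., 4:6] / anc[:, None]
            keep = np.maximum(r, 1.0 / r).max(axis=2) < ANCHOR_T
            t = t[keep]
        else:
            t = np.zeros((0, 7), np.float32)
        if len(t):
            gxy = t[:, 2:4]
            gxi = np.array([gw, gh], np.float32) - gxy
            jk = (gxy % 1.0 < g) & (gxy > 1.0)
            lm = (gxi % 1.0 < g) & (gxi > 1.0)
            mask = np.stack([np.ones(len(t), bool), jk[:, 0], jk[:, 1],
                             lm[:, 0], lm[:, 1]])
            t = np.tile(t[None], (5, 1, 1))[mask]
            offsets = (np.zeros((1, len(gxy), 2), np.float32)
                       + off[:, None])[mask]
        else:
            offsets = np.zeros((0, 2), np.float32)
        b = t[:, 0].astype(np.int64)
        c = t[:, 1].astype(np.int64)
        gxy = t[:, 2:4]
        gwh = t[:, 4:6]
        gij = (gxy - offsets).astype(np.int64)
        gi = np.clip(gij[:, 0], 0, gw - 1)
        gj = np.clip(gij[:, 1], 0, gh - 1)
        a = t[:, 6].astype(np.int64)
        indices.append((b, a, gj, gi))
        tboxes.append(np.concatenate([gxy - np.stack([gi, gj], axis=1), gwh],
                                     axis=1).astype(np.float32))
        tanch.append(anc[a])
        tclss.append(c)
    return TargetAssignment(indices, tboxes, tanch, tclss)


def assign_targets(labels, cfg: DetectorConfig) -> TargetAssignment:
    """Single-image convenience wrapper around :func:`build_targets`.

    ``labels`` is a list of NormalizedBox-like objects with
    ``(class_id, xc, yc, w, h)`` fields; grids derive from ``cfg.img_size``.
    """
    rows = np.array([[0, b.class_id, b.xc, b.yc, b.w, b.h] for b in labels],
                    dtype=np.float32).reshape(-1, 6)
    grids = [(cfg.img_size // s, cfg.img_size // s) for s in cfg.strides]
    return build_targets(rows, cfg, grids)


# --------------------------------------------------------------------- loss
def composite_loss(raw: list[Tensor], assignment: TargetAssignment,
                   weights: LossWeights = LossWeights(),
                   label_smoothing: float = 0.1,
                   num_classes: int | None = None
                   ) -> tuple[Tensor, dict[str, float]]:
    """Total loss over a batch of per-scale head outputs ``[B,3,H,W,5+nc]``."""
    nc = num_classes if num_classes is not None else raw[0].shape[-1] - 5
    cp, cn = 1.0 - 0.5 * label_smoothing, 0.5 * label_smoothing
    lcls = Tensor(0.0)
    lobj = Tensor(0.0)
    lbox = Tensor(0.0)
    n_pos = 0
    for s, p in enumerate(raw):
        b, a, gj, gi = assignment.indices[s]
        B, _, gh, gw, _ = p.shape
        tobj = np.zeros((B, 3, gh, gw), np.float32)
        if len(b):
            n_pos += len(b)
            ps = p[b, a, gj, gi]                       # [n, 5+nc]
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(assignment.anchors[s])
            pbox = concat([pxy, pwh], axis=1)
            ci = ciou_loss_t(pbox, assignment.tbox[s])
            lbox = lbox + (1.0 - ci).mean()
            tobj[b, a, gj, gi] = np.clip(ci.data, 0.0, None)
            if nc > 1:
                tc = np.full((len(b), nc), cn, np.float32)
                tc[np.arange(len(b)), assignment.tcls[s]] = cp
                lcls = lcls + bce_with_logits(ps[:, 5:], tc)
        lobj = lobj + bce_with_logits(p[..., 4], tobj) * OBJ_BALANCE[s]
    total = (weights.lambda_loc * lbox + weights.lambda_obj * lobj
             + weights.lambda_cls * lcls)
    parts = {"cls": float(lcls.data), "obj": float(lobj.data),
             "loc": float(lbox.data), "total": float(total.data),
             "n_pos": n_pos}
    return total, parts
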