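"""Independent brute-force oracles used by the tests.

Everything here is written directly from the mathematical definition as
explicit loops, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def conv2d_loop(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                stride: int = 1, pad: int = 0) -> np.ndarray:
    """Direct nested-loop cross-correlation. x:[C,H,W], w:[O,C,kh,kw]."""
    C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    ho = (H + 2 * pad - kh) // stride + 1
    wo = (W + 2 * pad - kw) // stride + 1
    out = np.zeros((O, ho, wo), dtype=np.float64)
    for o in range(O):
        for i in range(ho):
            for j in range(wo):
                acc = 0.0
                for c in range(C):
                    for di in range(kh):
                        for dj in range(kw):
                            acc += xp[c, i * stride + di, j * stride + dj] * w[o, c, di, dj]
                out[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def silu_np(x):
    return x / (1.0 + np.exp(-x))


def sigmoid_np(x):
    return 1.0 / (1.0 + np.exp(-x))


def esa_parallel_loop(x, params):
    """Full ESA forward composed from the loop convolution oracle."""
    d3 = silu_np(conv2d_loop(x, params.w3, params.b3, 1, 1))
    d5 = silu_np(conv2d_loop(x, params.w5, params.b5, 1, 2))
    cat = np.concatenate([d3, d5], axis=0)
    s = sigmoid_np(conv2d_loop(cat, params.w_fuse, params.b_fuse, 1, 0))
    return x + params.alpha * (x * s)


def esa_sequential_loop(x, params):
    h = silu_np(conv2d_loop(x, params.seq_w1, params.seq_b1, 1, 1))
    h = silu_np(conv2d_loop(h, params.seq_w2, params.seq_b2, 1, 1))
    s = sigmoid_np(conv2d_loop(h, params.seq_w3, params.seq_b3, 1, 1))
    return x + params.alpha * (x * s)


def iou_ref(a, b):
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    if ix2 <= ix1 or iy2 <= iy1:
        return 0.0
    inter = (ix2 - ix1) * (iy2 - iy1)
    area = ((a[2] - a[0]) * (a[3] - a[1])
            + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / area


def nms_ref(dets, conf, iou_thr):
    """Independent greedy suppression over (box, score, cls) tuples."""
    alive = [d for d in dets if d.score >= conf]
    alive.sort(key=lambda d: (-d.score, d.image_id, d.box))
    kept = []
    while alive:
        best = alive.pop(0)
        kept.append(best)
        alive = [d for d in alive
                 if d.class_id != best.class_id
                 or iou_ref(d.box, best.box) <= iou_thr]
    return kept


def match_ref(dets, gts, thr):
    """Score-descending greedy one-to-one matching (max-IoU gt wins)."""
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].score, dets[i].image_id, dets[i].box))
    used = set()
    tp = [False] * len(dets)
    for i in order:
        d = dets[i]
        cands = [(iou_ref(d.box, g.box), j) for j, g in enumerate(gts)
                 if j not in used and g.class_id == d.class_id
                 and g.image_id == d.image_id]
        cands = [(v, j) for v, j in cands if v >= thr]
        if cands:
            v, j = max(cands, key=lambda t: (t[0], -t[1]))
            used.add(j)
            tp[i] = True
    return tp, [j in used for j in range(len(gts))]


def ap_ref(tp_sorted, n_gt):
    """AP from TP flags already in descending-score order: rectangle sum
    over recall increments with the running max of future precision."""
    if n_gt == 0:
        return 0.0
    precisions, recalls = [], []
    t = f = 0
    for flag in tp_sorted:
        t += int(flag)
        f += int(not flag)
        precisions.append(t / (t + f))
        recalls.append(t / n_gt)
    ap = 0.0
    prev_r = 0.0
    for i, r in enumerate(recalls):
        if r > prev_r:
            best_p = max(precisions[i:])
            ap += (r - prev_r) * best_p
            prev_r = r
    return ap


def decode_loop(raw_scales, anchors, strides, img_size, conf_thr):
    """Nested-loop decode of per-scale [3, H, W, 5+nc] arrays."""
    dets = []
    for s, (p, stride) in enumerate(zip(raw_scales, strides)):
        na, H, W, no = p.shape
        nc = no - 5
        for a in range(na):
            for gy in range(H):
                for gx in range(W):
                    v = p[a, gy, gx]
                    obj = sigmoid_np(v[4])
                    cls = sigmoid_np(v[5:])
                    c = int(np.argmax(cls))
                    score = obj * cls[c]
                    if score < conf_thr:
                        continue
                    cx = (2 * sigmoid_np(v[0]) - 0.5 + gx) * stride
                    cy = (2 * sigmoid_np(v[1]) - 0.5 + gy) * stride
                    bw = (2 * sigmoid_np(v[2])) ** 2 * anchors[s][a][0]
                    bh = (2 * sigmoid_np(v[3])) ** 2 * anchors[s][a][1]
                    x1 = min(max(cx - bw / 2, 0), img_size)
                    y1 = min(max(cy - bh / 2, 0), img_size)
                    x2 = min(max(cx + bw / 2, 0), img_size)
                    y2 = min(max(cy + bh / 2, 0), img_size)
                    if x2 > x1 and y2 > y1:
                        dets.append(((x1, y1, x2, y2), float(score), c))
    return dets


def ciou_ref(a, b):
    """Term-by-term CIoU of two corner boxes."""
    i = iou_ref(a, b)
    cw = max(a[2], b[2]) - min(a[0], b[0])
    ch = max(a[3], b[3]) - min(a[1], b[1])
    c2 = cw ** 2 + ch ** 2
    rho2 = (((a[0] + a[2]) / 2 - (b[0] + b[2]) / 2) ** 2
            + ((a[1] + a[3]) / 2 - (b[1] + b[3]) / 2) ** 2)
    wa, ha = a[2] - a[0], a[3] - a[1]
    wb, hb = b[2] - b[0], b[3] - b[1]
    v = 4 / math.pi ** 2 * (math.atan(wa / ha) - math.atan(wb / hb)) ** 2
    alpha = v / (1 - i + v) if (1 - i + v) > 0 else 0.0
    return i - rho2 / c2 - alpha * v


def assign_ref(labels, anchors_px, strides, grid_sizes, ratio_thr=4.0):
    """Exhaustive enumeration over (scale, anchor, cell) triples.

    Returns the set of positives {(scale, anchor, gj, gi, label_index)}
    under the anchor-ratio test plus nearest-two-neighbor-cell expansion.
    """
    out = set()
    for li, (cls, xc, yc, w, h) in enumerate(labels):
        for s, (stride, (gh, gw)) in enumerate(zip(strides, grid_sizes)):
            gx, gy = xc * gw, yc * gh
            wg, hg = w * gw, h * gh
            for a, (aw, ah) in enumerate(anchors_px[s]):
                awg, ahg = aw / stride, ah / stride
                ratio = max(wg / awg, awg / wg, hg / ahg, ahg / hg)
                if ratio >= ratio_thr:
                    continue
                cells = {(int(gx), int(gy))}
                fx, fy = gx % 1, gy % 1
                if fx < 0.5 and gx > 1:
                    cells.add((int(gx) - 1, int(gy)))
                if fy < 0.5 and gy > 1:
                    cells.add((int(gx), int(gy) - 1))
                if fx > 0.5 and gx < gw - 1:
                    cells.add((int(gx) + 1, int(gy)))
                if fy > 0.5 and gy < gh - 1:
                    cells.add((int(gx), int(gy) + 1))
                for gi, gj in cells:
                    gi = min(max(gi, 0), gw - 1)
                    gj = min(max(gj, 0), gh - 1)
                    out.add((s, a, gj, gi, li))
    return out
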