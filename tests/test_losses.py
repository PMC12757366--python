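"""CIoU geometry, target assignment and the composite loss."""

import numpy as np
import pytest

from esadet import nn
from esadet.losses import (LossWeights, TargetAssignment, assign_targets,
                           build_targets, ciou, ciou_loss_t, composite_loss)
from esadet.metrics import iou
from esadet.model import DetectorConfig, build_detector
from esadet.data import NormalizedBox
from esadet.nn import Tensor

from oracles import assign_ref, ciou_ref, sigmoid_np

CFG = DetectorConfig(placement="none", num_classes=3, width_multiple=0.25,
                     depth_multiple=0.33, img_size=64)


class TestCiou:
    def test_identical_boxes_score_one(self):
        assert ciou((0, 0, 2, 3), (0, 0, 2, 3)) == pytest.approx(1.0, abs=1e-6)

    def test_distant_same_shape_boxes_negative(self):
        assert ciou((0, 0, 1, 1), (10, 10, 11, 11)) < 0.0

    def test_hand_evaluated_example(self):
        # IoU=1/7, rho^2=2, c^2=18, v=0 (same aspect ratio)
        expected = 1 / 7 - 2 / 18
        assert ciou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(expected, abs=1e-5)

    def test_matches_term_by_term_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0)
            b = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0)
            box_a = (a[0, 0], a[0, 1], a[1, 0] + 0.5, a[1, 1] + 0.5)
            box_b = (b[0, 0], b[0, 1], b[1, 0] + 0.5, b[1, 1] + 0.5)
            assert ciou(box_a, box_b) == pytest.approx(
                ciou_ref(box_a, box_b), abs=2e-4)

    def test_invariant_under_translation_and_scaling(self, rng):
        a = (1.0, 2.0, 4.0, 5.0)
        b = (2.0, 1.0, 6.0, 4.0)
        base = ciou(a, b)
        for _ in range(5):
            t = rng.uniform(-20, 20, 2)
            s = rng.uniform(0.1, 10)
            at = tuple(s * (np.array(a) + np.tile(t, 2)))
            bt = tuple(s * (np.array(b) + np.tile(t, 2)))
            assert ciou(at, bt) == pytest.approx(base, abs=1e-4)

    def test_never_exceeds_iou(self, rng):
        for _ in range(50):
            a = tuple(np.sort(rng.uniform(0, 8, 2))) + (0.0,)
            ax1, ax2, _ = a
            box_a = (ax1, 0.0, ax2 + 0.2, rng.uniform(1, 3))
            bx1, bx2 = np.sort(rng.uniform(0, 8, 2))
            box_b = (bx1, 0.5, bx2 + 0.2, rng.uniform(1.5, 4))
            assert ciou(box_a, box_b) <= iou(box_a, box_b) + 1e-7

    def test_equality_with_iou_iff_centered_same_aspect(self):
        a = (0.0, 0.0, 4.0, 2.0)
        b = (1.0, 0.5, 3.0, 1.5)   # same center, same aspect ratio 2:1
        assert ciou(a, b) == pytest.approx(iou(a, b), abs=1e-6)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ciou((0, 0, 0, 1), (0, 0, 1, 1))

    def test_tensor_version_agrees_with_scalar(self, rng):
        pred = rng.uniform(1, 5, (8, 4)).astype(np.float32)
        tgt = rng.uniform(1, 5, (8, 4)).astype(np.float32)
        vals = ciou_loss_t(Tensor(pred), tgt).data
        for k in range(8):
            def corners(v):
                return (v[0] - v[2] / 2, v[1] - v[3] / 2,
                        v[0] + v[2] / 2, v[1] + v[3] / 2)
            assert vals[k] == pytest.approx(
                ciou(corners(pred[k]), corners(tgt[k])), abs=2e-4)


class TestAssignment:
    def test_anchor_shaped_label_matches_its_own_scale(self):
        # label exactly equal to the scaled scale-1 anchor of a 64px input
        aw, ah = CFG.anchor_array()[1][0]
        lbl = [NormalizedBox(0.5, 0.5, aw / 64, ah / 64, 0)]
        a = assign_targets(lbl, CFG)
        scales_anchors = {(s, int(ai)) for s in range(3)
                          for ai in a.indices[s][1]}
        assert (1, 0) in scales_anchors

    def test_oversized_label_matches_nothing(self):
        lbl = [NormalizedBox(0.5, 0.5, 1.0, 1.0, 0)]
        cfg = DetectorConfig(placement="none", num_classes=3,
                             img_size=64,
                             anchors=(((1, 1), (1, 2), (2, 1)),) * 3)
        assert assign_targets(lbl, cfg).num_positives() == 0

    def test_empty_label_list_valid(self):
        a = assign_targets([], CFG)
        assert a.num_positives() == 0

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels = [(int(r.integers(0, 3)), *r.uniform(0.2, 0.8, 2),
                       *r.uniform(0.05, 0.5, 2)) for _ in range(4)]
            rows = np.array([[0, *lab] for lab in labels], np.float32)
            grids = [(64 // s, 64 // s) for s in CFG.strides]
            got = build_targets(rows, CFG, grids)
            got_set = set()
            for s in range(3):
                b, a, gj, gi = got.indices[s]
                for k in range(len(b)):
                    got_set.add((s, int(a[k]), int(gj[k]), int(gi[k])))
            ref = assign_ref(labels, CFG.anchor_array(), CFG.strides, grids)
            ref_set = {(s, a, gj, gi) for (s, a, gj, gi, _) in ref}
            assert got_set == ref_set


def perfect_raw(cfg, assignment: TargetAssignment, shape_per_scale):
    """Raw logits that decode exactly onto the assigned targets."""
    raws = []
    for s, (gh, gw) in enumerate(shape_per_scale):
        p = np.full((1, 3, gh, gw, 5 + cfg.num_classes), -20.0, np.float32)
        b, a, gj, gi = assignment.indices[s]
        for k in range(len(b)):
            dx, dy, w, h = assignment.tbox[s][k]
            aw, ah = assignment.anchors[s][k]
            def logit(x):
                x = np.clip(x, 1e-6, 1 - 1e-6)
                return np.log(x / (1 - x))
            p[b[k], a[k], gj[k], gi[k], 0] = logit((dx + 0.5) / 2)
            p[b[k], a[k], gj[k], gi[k], 1] = logit((dy + 0.5) / 2)
            p[b[k], a[k], gj[k], gi[k], 2] = logit(np.sqrt(w / aw) / 2)
            p[b[k], a[k], gj[k], gi[k], 3] = logit(np.sqrt(h / ah) / 2)
            p[b[k], a[k], gj[k], gi[k], 4] = 20.0
            p[b[k], a[k], gj[k], gi[k], 5 + assignment.tcls[s][k]] = 20.0
        raws.append(Tensor(p))
    return raws


class TestCompositeLoss:
    grids = [(64 // s, 64 // s) for s in CFG.strides]
    targets = np.array([[0, 1, 0.4, 0.5, 0.3, 0.25],
                        [0, 2, 0.7, 0.3, 0.1, 0.15]], np.float32)

    def assignment(self):
        return build_targets(self.targets, CFG, self.grids)

    def test_perfect_fit_drives_loc_to_zero(self):
        a = self.assignment()
        raw = perfect_raw(CFG, a, self.grids)
        _, parts = composite_loss(raw, a, label_smoothing=0.1)
        assert parts["loc"] < 1e-3
        assert np.isfinite(parts["total"]) and parts["total"] >= 0

    def test_weight_linearity_and_homogeneity(self, rng):
        a = self.assignment()
        raw = [Tensor(rng.normal(0, 1, (1, 3, gh, gw, 8)).astype(np.float32))
               for gh, gw in self.grids]
        loc_only, p1 = composite_loss(raw, a, LossWeights(0.0, 0.0, 1.0))
        assert loc_only.item() == pytest.approx(p1["loc"], abs=1e-6)
        t1, _ = composite_loss(raw, a, LossWeights(0.5, 1.0, 0.05))
        t2, _ = composite_loss(raw, a, LossWeights(1.0, 2.0, 0.10))
        assert t2.item() == pytest.approx(2 * t1.item(), rel=1e-5)

    def test_no_positives_keeps_objectness_only(self, rng):
        empty = build_targets(np.zeros((0, 6), np.float32), CFG, self.grids)
        raw = [Tensor(rng.normal(size=(1, 3, gh, gw, 8)).astype(np.float32))
               for gh, gw in self.grids]
        total, parts = composite_loss(raw, empty)
        assert parts["cls"] == 0.0 and parts["loc"] == 0.0
        assert parts["obj"] > 0.0 and np.isfinite(total.item())

    def test_matches_loop_oracle_on_tiny_case(self, rng):
        """Independent per-cell reimplementation of all three terms."""
        a = self.assignment()
        raw = [Tensor(rng.normal(0, 1.5, (1, 3, gh, gw, 8)).astype(np.float32))
               for gh, gw in self.grids]
        weights = LossWeights(0.5, 1.0, 0.05)
        total, parts = composite_loss(raw, a, weights, label_smoothing=0.1)

        balance = (4.0, 1.0, 0.4)
        lcls = lobj = lloc = 0.0
        n_cls_terms = 0
        for s, p in enumerate(raw):
            arr = p.data[0]
            b, an, gj, gi = a.indices[s]
            tobj = np.zeros(arr.shape[:3])
            cls_sum = 0.0
            loc_sum = 0.0
            for k in range(len(b)):
                v = arr[an[k], gj[k], gi[k]]
                px = 2 * sigmoid_np(v[0]) - 0.5
                py = 2 * sigmoid_np(v[1]) - 0.5
                pw = (2 * sigmoid_np(v[2])) ** 2 * a.anchors[s][k][0]
                ph = (2 * sigmoid_np(v[3])) ** 2 * a.anchors[s][k][1]
                tx, ty, tw, th = a.tbox[s][k]
                ci = ciou_ref((px - pw / 2, py - ph / 2, px + pw / 2, py + ph / 2),
                              (tx - tw / 2, ty - th / 2, tx + tw / 2, ty + th / 2))
                loc_sum += 1 - ci
                tobj[an[k], gj[k], gi[k]] = max(ci, 0.0)
                tcl = np.full(3, 0.05)
                tcl[a.tcls[s][k]] = 0.95
                pr = sigmoid_np(v[5:])
                cls_sum += -np.mean(tcl * np.log(pr) + (1 - tcl) * np.log(1 - pr))
                n_cls_terms += 1
            if len(b):
                lloc += loc_sum / len(b)
                lcls += cls_sum / len(b)
            pr_obj = sigmoid_np(arr[..., 4])
            eps = 1e-12
            bce = -(tobj * np.log(pr_obj + eps)
                    + (1 - tobj) * np.log(1 - pr_obj + eps))
            lobj += bce.mean() * balance[s]
        assert parts["loc"] == pytest.approx(lloc, rel=2e-3, abs=2e-3)
        assert parts["obj"] == pytest.approx(lobj, rel=2e-3, abs=2e-3)
        assert parts["cls"] == pytest.approx(lcls, rel=2e-3, abs=2e-3)
        ref_total = 0.05 * lloc + 1.0 * lobj + 0.5 * lcls
        assert total.item() == pytest.approx(ref_total, rel=5e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_step_decreases_loss(self, seed):
        nn.seed_all(seed)
        model = build_detector(CFG)
        rng = np.random.default_rng(seed)
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        a = self.assignment()
        opt = nn.AdamW(model.parameters(), lr=5e-3, weight_decay=0.0)
        losses = []
        for _ in range(3):
            opt.zero_grad()
            outs = model.forward(x)
            loss, _ = composite_loss(outs, a)
            losses.append(loss.item())
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0]

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)
        with pytest.raises(ValueError):
            LossWeights(-1, 1, 1)
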