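"""Label I/O, letterboxing, augmentations and dataset splits."""

import numpy as np
import pytest

from esadet.data import (LabelParseError, LabeledImage,
                         NormalizedBox, hflip, hsv_jitter,
                         kfold_split, mixup, mosaic, normalize_and_resize,
                         read_yolo_labels, rotate, stratified_split,
                         write_yolo_labels)


def box(xc=0.5, yc=0.5, w=0.2, h=0.3, cls=0):
    return NormalizedBox(xc, yc, w, h, cls)


def boxes_close(a, b, tol=1e-9):
    return (len(a) == len(b) and all(
        x.class_id == y.class_id
        and all(abs(getattr(x, f) - getattr(y, f)) <= tol
                for f in ("xc", "yc", "w", "h"))
        for x, y in zip(a, b)))


def blob_image(size=64, cls=0, cx=0.5, cy=0.5, r=0.15):
    """Grey canvas with a bright rectangle and its exact box label."""
    img = np.full((3, size, size), 0.3, np.float32)
    x1, x2 = int((cx - r) * size), int((cx + r) * size)
    y1, y2 = int((cy - r) * size), int((cy + r) * size)
    img[:, y1:y2, x1:x2] = 0.9
    b = NormalizedBox((x1 + x2) / (2 * size), (y1 + y2) / (2 * size),
                      (x2 - x1) / size, (y2 - y1) / size, cls)
    return LabeledImage(img, [b], "blob")


class TestLabelIO:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("0 0.5 0.5 0.2 0.3\n")
        (b,) = read_yolo_labels(p)
        assert (b.class_id, b.xc, b.yc, b.w, b.h) == (0, 0.5, 0.5, 0.2, 0.3)

    def test_empty_file_is_background(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("")
        assert read_yolo_labels(p) == []

    def test_roundtrip_of_many_random_boxes(self, tmp_path, rng):
        boxes = []
        for _ in range(100):
            w, h = rng.uniform(0.01, 0.4, 2)
            xc = rng.uniform(w / 2, 1 - w / 2)
            yc = rng.uniform(h / 2, 1 - h / 2)
            boxes.append(NormalizedBox(xc, yc, w, h, int(rng.integers(0, 3))))
        p = tmp_path / "r.txt"
        write_yolo_labels(boxes, p)
        back = read_yolo_labels(p)
        for a, b in zip(boxes, back):
            assert a.class_id == b.class_id
            for f in ("xc", "yc", "w", "h"):
                assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-6)

    @pytest.mark.parametrize("row,msg", [
        ("0 0.5 0.5", "5 fields"),
        ("0 1.5 0.5 0.2 0.2", "outside"),
        ("7 0.5 0.5 0.2 0.2", "out of range"),
        ("x 0.5 0.5 0.2 0.2", "invalid literal"),
    ])
    def test_malformed_rows_carry_line_number(self, tmp_path, row, msg):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n" + row + "\n")
        with pytest.raises(LabelParseError, match=r":2.*" + msg):
            read_yolo_labels(p, num_classes=3)


class TestLetterbox:
    def test_full_range_square_at_target_is_identity(self, rng):
        img = rng.random((3, 64, 64)).astype(np.float32)
        img.flat[0], img.flat[1] = 0.0, 1.0     # pin the intensity range
        out = normalize_and_resize(img, 64, [box()])
        assert np.allclose(out.image, img, atol=1e-6)
        assert boxes_close(out.boxes, [box()])

    def test_landscape_letterboxing_compresses_y(self):
        img = np.zeros((32, 64), np.float32)
        img[0, 0] = 1.0
        b = box(0.5, 0.5, 0.4, 0.5)
        out = normalize_and_resize(img, 64, [b])
        assert out.image.shape == (3, 64, 64)
        pad = 114 / 255
        assert np.allclose(out.image[:, :16, :], pad, atol=1e-6)
        assert np.allclose(out.image[:, 48:, :], pad, atol=1e-6)
        nb = out.boxes[0]
        # content occupies rows 16..48: yc stays centered, h halves
        assert nb.xc == pytest.approx(0.5) and nb.yc == pytest.approx(0.5)
        assert nb.w == pytest.approx(0.4, abs=1e-6)
        assert nb.h == pytest.approx(0.25, abs=1e-6)

    def test_constant_image_maps_to_half(self):
        out = normalize_and_resize(np.full((40, 40), 7.0), 64)
        inner = out.image[:, 12:52, 12:52]
        assert np.allclose(inner, 0.5, atol=1e-6)
        assert not np.isnan(out.image).any()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_resize(np.zeros((0, 4)), 64)


class TestFlip:
    def test_double_flip_is_identity(self, rng):
        s = LabeledImage(rng.random((3, 16, 16)).astype(np.float32),
                         [box(0.3, 0.6, 0.1, 0.2, 1)])
        ss = hflip(hflip(s))
        assert np.array_equal(ss.image, s.image)
        assert boxes_close(ss.boxes, s.boxes)

    def test_box_on_axis_is_fixed_point(self):
        s = LabeledImage(np.zeros((3, 8, 8), np.float32), [box(xc=0.5)])
        assert hflip(s).boxes[0].xc == 0.5

    def test_flip_matches_pixel_oracle(self):
        s = blob_image(cx=0.3)
        f = hflip(s)
        cols = np.flatnonzero((f.image[0] > 0.6).any(axis=0))
        x1, x2 = cols[0], cols[-1] + 1
        b = f.boxes[0]
        assert b.xc * 64 == pytest.approx((x1 + x2) / 2, abs=0.51)
        assert b.w * 64 == pytest.approx(x2 - x1, abs=1.01)


class TestRotate:
    def test_zero_angle_identity(self, rng):
        s = LabeledImage(rng.random((3, 16, 16)).astype(np.float32), [box()])
        r = rotate(s, 0.0)
        assert np.array_equal(r.image, s.image) and r.boxes == s.boxes

    @pytest.mark.parametrize("angle", [-10, -7, 3, 10])
    def test_centered_square_grows_by_corner_formula(self, angle):
        s = LabeledImage(np.zeros((3, 100, 100), np.float32),
                         [box(0.5, 0.5, 0.3, 0.3)])
        r = rotate(s, angle)
        th = np.radians(angle)
        factor = abs(np.cos(th)) + abs(np.sin(th))
        nb = r.boxes[0]
        assert nb.xc == pytest.approx(0.5, abs=1e-6)
        assert nb.yc == pytest.approx(0.5, abs=1e-6)
        assert nb.w == pytest.approx(0.3 * factor, abs=1e-6)
        assert nb.h == pytest.approx(0.3 * factor, abs=1e-6)

    def test_rotated_mask_contained_in_transformed_box(self):
        s = blob_image(size=100, cx=0.4, cy=0.55, r=0.12)
        r = rotate(s, 7.0)
        mask = (r.image[0] > 0.6)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        b = r.boxes[0]
        x1, y1, x2, y2 = b.corners(100, 100)
        assert x1 <= cols[0] + 1 and x2 >= cols[-1] - 1
        assert y1 <= rows[0] + 1 and y2 >= rows[-1] - 1


class TestHsv:
    def test_zero_gains_is_near_identity(self, rng):
        s = LabeledImage(rng.random((3, 12, 12)).astype(np.float32), [box()])
        out = hsv_jitter(s, gains=(0, 0, 0), rng=np.random.default_rng(0))
        assert np.abs(out.image - s.image).max() <= 1 / 255

    def test_boxes_untouched(self, rng):
        s = LabeledImage(rng.random((3, 12, 12)).astype(np.float32),
                         [box(0.2, 0.8, 0.1, 0.1, 2)])
        assert hsv_jitter(s, rng=np.random.default_rng(1)).boxes == s.boxes

    def test_value_channel_mean_shift_bounded_by_gain(self):
        base = np.random.default_rng(3).random((3, 24, 24)).astype(np.float32)
        s = LabeledImage(base, [])
        for seed in range(100):
            out = hsv_jitter(s, gains=(0.015,) * 3,
                             rng=np.random.default_rng(seed))
            vin = np.moveaxis(s.image, 0, -1).max(axis=-1).mean()
            vout = np.moveaxis(out.image, 0, -1).max(axis=-1).mean()
            assert abs(vout - vin) <= 0.015 * vin + 1e-3


class TestMosaic:
    def test_center_pinned_to_middle_places_quadrant_boxes(self):
        s = blob_image(size=64, r=0.1)

        class PinnedRng:
            def uniform(self, a, b, size=None):
                return 0.5
            def random(self):
                return 0.5
        out = mosaic([s] * 4, 64, PinnedRng())
        assert out.image.shape == (3, 64, 64)
        assert len(out.boxes) == 4
        centers = sorted((round(b.xc, 2), round(b.yc, 2)) for b in out.boxes)
        assert centers == [(0.25, 0.25), (0.25, 0.75),
                           (0.75, 0.25), (0.75, 0.75)]
        for b in out.boxes:
            assert b.w == pytest.approx(s.boxes[0].w / 2, abs=0.02)

    def test_box_conservation_bound(self, rng):
        samples = [blob_image(cx=0.3 + 0.1 * i, cy=0.4, r=0.1)
                   for i in range(4)]
        for seed in range(10):
            out = mosaic(samples, 64, np.random.default_rng(seed))
            assert len(out.boxes) <= sum(len(s.boxes) for s in samples)
            for b in out.boxes:
                assert 0 <= b.xc <= 1 and 0 <= b.yc <= 1 and b.w > 0

    def test_seeded_box_remap_matches_pixel_oracle(self):
        s = blob_image(size=64, cx=0.5, cy=0.5, r=0.12)
        out = mosaic([s] * 4, 64, np.random.default_rng(4))
        mask = out.image[0] > 0.55
        for b in out.boxes:
            x1, y1, x2, y2 = b.corners(64, 64)
            region = mask[int(np.floor(y1)):int(np.ceil(y2)),
                          int(np.floor(x1)):int(np.ceil(x2))]
            assert region.mean() > 0.5  # boxes cover the bright patches

    def test_needs_exactly_four(self):
        with pytest.raises(ValueError):
            mosaic([blob_image()] * 3, 64, np.random.default_rng(0))


class TestMixup:
    def test_lambda_one_keeps_first_image_with_union_labels(self):
        a, b = blob_image(cls=0), blob_image(cls=1, cx=0.3)
        out = mixup(a, b, lam=1.0)
        assert np.allclose(out.image, a.image)
        assert len(out.boxes) == 2

    def test_box_count_is_sum(self, rng):
        a, b = blob_image(cls=0), blob_image(cls=2, cx=0.7)
        out = mixup(a, b, rng=np.random.default_rng(2))
        assert len(out.boxes) == len(a.boxes) + len(b.boxes)

    def test_pixel_mean_is_convex_combination(self):
        a, b = blob_image(cx=0.3), blob_image(cx=0.7)
        lam = 0.37
        out = mixup(a, b, lam=lam)
        expect = lam * a.image.mean() + (1 - lam) * b.image.mean()
        assert out.image.mean() == pytest.approx(expect, abs=1e-6)


class TestSplits:
    def test_exact_stratification_small(self):
        items = list(range(30))
        classes = [i % 3 for i in items]
        tr, va = stratified_split(items, classes, 0.8, seed=1)
        assert len(tr) == 24 and len(va) == 6
        for c in range(3):
            assert sum(1 for i in tr if i % 3 == c) == 8

    def test_partition_properties(self):
        items = list(range(50))
        classes = [i % 3 for i in items]
        tr, va = stratified_split(items, classes, 0.8, seed=2)
        assert sorted(tr + va) == items and not set(tr) & set(va)

    def test_figshare_counts_largest_remainder(self):
        classes = [0] * 1426 + [1] * 708 + [2] * 930
        items = list(range(len(classes)))
        tr, _ = stratified_split(items, classes, 0.8, seed=0)
        per = [sum(1 for i in tr if classes[i] == c) for c in range(3)]
        assert per == [1141, 566, 744]

    def test_seed_reproducibility(self):
        items = list(range(40))
        classes = [i % 2 for i in items]
        assert stratified_split(items, classes, seed=9) == \
            stratified_split(items, classes, seed=9)

    def test_kfold_balance_and_coverage(self):
        classes = [0] * 1426 + [1] * 708 + [2] * 930
        items = list(range(len(classes)))
        folds = kfold_split(items, classes, k=5, seed=3)
        seen = []
        for _, val in folds:
            seen.extend(val)
            for c in range(3):
                n = sum(1 for i in val if classes[i] == c)
                total = [1426, 708, 930][c]
                assert abs(n - total / 5) <= 1
        assert sorted(seen) == items

    def test_kfold_identity_case_equal_sizes(self):
        items = list(range(30))
        classes = [i % 3 for i in items]
        folds = kfold_split(items, classes, k=5, seed=0)
        assert all(len(val) == 6 for _, val in folds)

    def test_kfold_rejects_k1(self):
        with pytest.raises(ValueError):
            kfold_split([1, 2], [0, 0], k=1)


class TestDataset:
    def test_open_and_load(self, micro_datasets):
        train, val = micro_datasets
        assert train.num_classes == 3
        s = train.load(0, 64)
        assert s.image.shape == (3, 64, 64)
        assert s.boxes and all(0 <= b.class_id < 3 for b in s.boxes)

    def test_augmented_stream_deterministic(self, micro_datasets):
        from esadet.data import augmented_sample
        train, _ = micro_datasets
        a = augmented_sample(train, 0, 64, np.random.default_rng(5))
        b = augmented_sample(train, 0, 64, np.random.default_rng(5))
        assert np.array_equal(a.image, b.image)
        assert a.boxes == b.boxes
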