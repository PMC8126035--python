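import dataclasses

import numpy as np
import pytest
from skimage import draw

from hemocount import (
    ObjectDescriptors,
    RGBImage,
    ShapeFilter,
    SyntheticSpec,
    ValidationError,
    calibrate_filter,
    clean_mask,
    filter_objects,
    generate_field,
    label_objects,
    match_to_truth,
    shape_descriptors,
)


def _descriptors_of_mask(mask):
    return shape_descriptors(label_objects(mask))


class TestCleanMask:
    def test_radius0_no_fill_is_identity(self, rng):
        mask = rng.random((15, 15)) < 0.3
        np.testing.assert_array_equal(clean_mask(mask, 0, False), mask)

    def test_closing_merges_nearby_pixels(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 2] = mask[3, 4] = True  # distance 2 apart
        labels = label_objects(clean_mask(mask, 1, False))
        assert labels.max() == 1

    def test_fill_holes_solidifies_ring(self):
        mask = np.zeros((21, 21), dtype=bool)
        rr, cc = draw.circle_perimeter(10, 10, 6)
        mask[rr, cc] = True
        filled = clean_mask(mask, 0, True)
        disk_rr, disk_cc = draw.disk((10, 10), 6)
        assert filled[disk_rr, disk_cc].all()


class TestLabel:
    def test_empty_mask(self):
        assert label_objects(np.zeros((5, 5), dtype=bool)).max() == 0

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_objects(mask, 8).max() == 1
        assert label_objects(mask, 4).max() == 2

    def test_three_disjoint_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        for r0 in (0, 7, 14):
            mask[r0 : r0 + 3, 0:3] = True
        assert label_objects(mask).max() == 3

    def test_label_conservation(self, rng):
        mask = clean_mask(rng.random((40, 40)) < 0.4, 1, True)
        objs = _descriptors_of_mask(mask)
        assert sum(o.area for o in objs) == int(mask.sum())


class TestShapeDescriptors:
    def test_filled_square(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        (obj,) = _descriptors_of_mask(mask)
        assert (obj.area, obj.width, obj.height) == (9, 3, 3)
        assert obj.solidity == 1.0
        assert obj.centroid == (3.0, 3.0)

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        (obj,) = _descriptors_of_mask(mask)
        assert (obj.area, obj.width, obj.height, obj.solidity) == (1, 1, 1, 1.0)
        assert obj.circularity > 0

    def test_rasterized_disk(self):
        mask = np.zeros((31, 31), dtype=bool)
        rr, cc = draw.disk((15, 15), 10)
        mask[rr, cc] = True
        (obj,) = _descriptors_of_mask(mask)
        assert 0.85 <= obj.circularity <= 1.15
        assert obj.solidity >= 0.95

    def test_invariants_on_random_blobs(self, rng):
        mask = clean_mask(rng.random((50, 50)) < 0.35, 1, True)
        for obj in _descriptors_of_mask(mask):
            assert obj.area >= 1
            assert 0 < obj.solidity <= 1
            assert obj.circularity > 0
            assert obj.area <= obj.width * obj.height

    def test_transpose_maps_detections(self, rng):
        mask = clean_mask(rng.random((30, 44)) < 0.35, 1, True)
        objs = _descriptors_of_mask(mask)
        objs_t = _descriptors_of_mask(mask.T)
        assert len(objs) == len(objs_t)
        cents = sorted(o.centroid for o in objs)
        cents_t = sorted((c, r) for r, c in (o.centroid for o in objs_t))
        assert cents == pytest.approx(cents_t)


def _random_object(rng, label):
    return ObjectDescriptors(
        label=label,
        area=int(rng.integers(1, 400)),
        width=int(rng.integers(1, 30)),
        height=int(rng.integers(1, 30)),
        perimeter=float(rng.uniform(4, 100)),
        convex_area=500,
        circularity=float(rng.uniform(0.1, 1.15)),
        solidity=float(rng.uniform(0.1, 1.0)),
        centroid=(0.0, 0.0),
    )


class TestFilterObjects:
    def test_permissive_filter_keeps_all(self, rng):
        objs = [_random_object(rng, i) for i in range(10)]
        res = filter_objects(objs, ShapeFilter())
        assert res.count == 10 and not res.rejected

    def test_area_rejection_names_criterion(self):
        obj = dataclasses.replace(_random_object(np.random.default_rng(0), 1), area=9)
        res = filter_objects([obj], ShapeFilter(min_area=10))
        assert res.count == 0
        assert res.rejected[0][1] == "area"

    def test_against_brute_force_oracle(self, rng):
        objs = [_random_object(rng, i) for i in range(20)]
        f = ShapeFilter(
            min_area=50, max_area=300, min_width=3, max_width=25,
            min_height=3, max_height=25, min_circularity=0.4, min_solidity=0.5,
        )
        res = filter_objects(objs, f)
        expected_kept = [
            o for o in objs
            if f.min_area <= o.area <= f.max_area
            and f.min_width <= o.width <= f.max_width
            and f.min_height <= o.height <= f.max_height
            and o.circularity >= f.min_circularity
            and o.solidity >= f.min_solidity
        ]
        assert [o.label for o in res.kept] == [o.label for o in expected_kept]
        # first-failure order: area, width, height, circularity, solidity
        order = ["area", "width", "height", "circularity", "solidity"]
        for obj, crit in res.rejected:
            fails = []
            if not (f.min_area <= obj.area <= f.max_area):
                fails.append("area")
            if not (f.min_width <= obj.width <= f.max_width):
                fails.append("width")
            if not (f.min_height <= obj.height <= f.max_height):
                fails.append("height")
            if obj.circularity < f.min_circularity:
                fails.append("circularity")
            if obj.solidity < f.min_solidity:
                fails.append("solidity")
            assert crit == min(fails, key=order.index)

    def test_relaxing_filter_never_decreases_count(self, rng):
        objs = [_random_object(rng, i) for i in range(30)]
        tight = ShapeFilter(min_area=80, max_area=200, min_circularity=0.6)
        loose = ShapeFilter(min_area=40, max_area=300, min_circularity=0.3)
        assert filter_objects(objs, loose).count >= filter_objects(objs, tight).count

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            ShapeFilter(min_area=10, max_area=5)
        with pytest.raises(ValidationError):
            ShapeFilter(min_circularity=1.5)


class TestCalibrateFilter:
    def _obj(self, area):
        return ObjectDescriptors(
            label=1, area=area, width=10, height=10, perimeter=30.0,
            convex_area=area, circularity=0.9, solidity=0.95, centroid=(0, 0),
        )

    def test_margin_arithmetic(self):
        f = calibrate_filter([self._obj(100), self._obj(200)], margin=0.5)
        assert (f.min_area, f.max_area) == (50.0, 300.0)

    def test_zero_margin_is_observed_extremes(self):
        f = calibrate_filter([self._obj(100), self._obj(200)], margin=0.0)
        assert (f.min_area, f.max_area) == (100.0, 200.0)
        assert f.min_circularity == pytest.approx(0.9)

    def test_single_object_warns(self):
        with pytest.warns(UserWarning, match="single object"):
            calibrate_filter([self._obj(100)])

    def test_calibrated_filter_keeps_training_objects(self, rng):
        objs = [self._obj(int(a)) for a in rng.integers(50, 250, size=8)]
        f = calibrate_filter(objs, margin=0.5)
        assert filter_objects(objs, f).count == len(objs)


class TestCountHemocytes:
    def test_blank_white_field_counts_zero(self, trained_counter):
        blank = RGBImage(np.full((100, 100, 3), 250, dtype=np.uint8), id="blank")
        assert trained_counter.detect(blank).count == 0

    def test_planted_cells_recovered_exactly(self, trained_counter, small_spec):
        spec = small_spec.replace(hemocyte_count=4, nucleus_count=0, fiber_count=0)
        img, truth = generate_field(spec, seed=555)
        res = trained_counter.detect(img)
        assert res.count == 4
        m = match_to_truth([o.centroid for o in res.kept], truth, slack=5.0)
        assert m["tp"] == 4 and m["fp"] == 0

    def test_confounders_rejected(self, trained_counter, small_spec):
        spec = small_spec.replace(hemocyte_count=3)
        img, truth = generate_field(spec, seed=777)
        res = trained_counter.detect(img)
        m = match_to_truth([o.centroid for o in res.kept], truth)
        assert abs(res.count - 3) <= 1
        assert m["fp"] <= 1
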