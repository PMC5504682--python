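"""Cell detection and morphometry: components, hull ratio, rectangle, tuning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rodquant as rq
from rodquant.cells import candidate_components, shape_complexity
from conftest import single_cell_image, sweep_min_rect_area


def shoelace(poly):
    x, y = np.asarray(poly, dtype=float).T
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestCandidateComponents:
    def test_three_disjoint_cells_give_three_components(self):
        img = np.zeros((64, 64))
        img[10:20, 10:30] = 100
        img[30:40, 10:30] = 100
        img[45:55, 40:55] = 100
        labeled = candidate_components(img, blur_sigma=0, threshold=50)
        assert labeled.max() == 3

    def test_all_background_gives_zero_components(self):
        labeled = candidate_components(np.zeros((64, 64)), 0, 50)
        assert labeled.max() == 0

    def test_border_touching_component_removed(self):
        img = np.zeros((64, 64))
        img[0:10, 10:30] = 100  # touches the top border
        img[30:40, 10:30] = 100
        labeled = candidate_components(img, 0, 50)
        assert labeled.max() == 1

    def test_sub_noise_floor_speck_removed(self):
        img = np.zeros((64, 64))
        img[30:32, 30:32] = 100  # 4 px < 5 px floor
        assert candidate_components(img, 0, 50).max() == 0


class TestShapeComplexity:
    def test_filled_rectangle_is_convex(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 5:15] = True
        assert shape_complexity(mask) == pytest.approx(1.0, abs=0.02)

    def test_single_pixel_defined_as_one(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        assert shape_complexity(mask) == 1.0

    def test_l_shape_matches_polygon_oracle(self):
        mask = np.zeros((40, 40), bool)
        mask[0:30, 0:10] = True
        mask[0:10, 0:30] = True
        n_px = mask.sum()
        # convex hull of the L outline, on the unit-square pixel model
        hull_poly = [(-0.5, -0.5), (29.5, -0.5), (29.5, 9.5), (9.5, 29.5), (-0.5, 29.5)]
        oracle = shoelace(hull_poly) / n_px
        ratio = shape_complexity(mask)
        assert ratio == pytest.approx(oracle, rel=1e-9)
        assert ratio > 1.0


class TestMinAreaRect:
    def test_axis_aligned_lattice(self):
        xs, ys = np.meshgrid(np.arange(50), np.arange(10))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        rect = rq.min_area_rect(pts)
        assert abs(rect.length - 50) <= 1
        assert abs(rect.width - 10) <= 1
        assert rect.angle == pytest.approx(0.0, abs=1e-6)

    def test_rotation_preserves_size_and_reports_angle(self):
        xs, ys = np.meshgrid(np.arange(50), np.arange(10))
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        base = rq.min_area_rect(pts)
        theta = math.radians(30)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        rect = rq.min_area_rect(pts @ rot.T)
        assert rect.length == pytest.approx(base.length, rel=0.02)
        assert rect.width == pytest.approx(base.width, rel=0.02)
        assert rect.angle == pytest.approx(30.0, abs=1.0)

    def test_matches_brute_force_sweep_on_random_clouds(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = rng.integers(3, 40)
            pts = rng.normal(size=(n, 2)) * rng.uniform(1, 20, size=2)
            rect = rq.min_area_rect(pts)
            oracle = sweep_min_rect_area(pts)
            assert rect.length * rect.width <= oracle * (1 + 1e-3)
            assert rect.length * rect.width >= oracle * (1 - 1e-3)

    def test_collinear_points_have_zero_width(self):
        pts = np.column_stack([np.arange(10), 2.0 * np.arange(10)])
        rect = rq.min_area_rect(pts)
        assert rect.width == 0.0
        assert rect.length == pytest.approx(9 * math.sqrt(5), rel=1e-9)
        assert rect.angle == pytest.approx(math.degrees(math.atan2(2, 1)), abs=1e-6)

    def test_single_point_degenerates(self):
        assert rq.min_area_rect([(3.0, 4.0)]) == (0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(0.0, 179.0),
    )
    def test_area_is_rotation_invariant(self, seed, angle):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, size=(rng.integers(3, 30), 2))
        theta = math.radians(angle)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        a0 = rq.min_area_rect(pts)
        a1 = rq.min_area_rect(pts @ rot.T)
        assert a0.length * a0.width == pytest.approx(a1.length * a1.width, rel=1e-6, abs=1e-9)


class TestAutoTune:
    def test_clean_field_reaches_ratio_one(self, cell_field, default_limits):
        _, image, _ = cell_field
        tuning = rq.auto_tune(image, default_limits)
        assert tuning.ratio == 1.0
        assert tuning.detected == tuning.candidates == 50

    def test_debris_lowers_ratio_by_known_amount(self, default_limits):
        params = rq.CellFieldParams(n_cells=15, noise_sd=20.0, seed=21)
        image, truths = rq.generate_cell_field(params)
        # paint 5 round blobs (elongation ~1, below min_elongation) clear of cells
        rng = np.random.default_rng(3)
        yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
        placed = 0
        while placed < 5:
            cx, cy = rng.uniform(40, image.shape[1] - 40, size=2)
            if all(
                math.hypot(cx - t.center[0], cy - t.center[1]) > t.length / 2 + 30
                for t in truths
            ):
                image = image + params.cell_intensity * (
                    np.hypot(xx - cx, yy - cy) <= 12
                )
                placed += 1
        tuning = rq.auto_tune(image, default_limits)
        assert tuning.candidates == 20
        assert tuning.detected == 15
        assert tuning.ratio == pytest.approx(15 / 20)

    def test_noise_only_image_raises(self):
        # no structure at the scale of a cell: nothing reaches the area window
        rng = np.random.default_rng(8)
        noise = rng.normal(100.0, 30.0, size=(64, 64))
        limits = rq.DetectionLimits(min_area=400, max_area=5000)
        with pytest.raises(rq.NoCellsFoundError):
            rq.auto_tune(noise, limits)

    def test_detected_never_exceeds_candidates(self, cell_field, default_limits):
        _, image, _ = cell_field
        tuning = rq.auto_tune(image, default_limits)
        assert 0 <= tuning.detected <= tuning.candidates
        assert 0.0 <= tuning.ratio <= 1.0


class TestMeasureCells:
    def test_micron_conversion(self, default_limits):
        image, _ = single_cell_image(length=50, width=10, angle=0)
        ms = rq.measure_cells(image, default_limits, pixel_size=0.1)
        assert len(ms) == 1
        assert ms[0].length_um == pytest.approx(5.0, abs=0.1)
        assert ms[0].width_um == pytest.approx(1.0, abs=0.1)

    def test_population_recovery_from_truth(self, cell_field, default_limits):
        """>= 95% of cells detected; mean length within 3% of generator truth."""
        params, image, truths = cell_field
        ms = rq.measure_cells(image, default_limits, pixel_size=params.pixel_size)
        assert len(ms) >= 0.95 * len(truths)
        true_mean = np.mean([t.length for t in truths])
        measured_mean = np.mean([m.length_px for m in ms])
        assert measured_mean == pytest.approx(true_mean, rel=0.03)

    def test_measurement_invariants(self, cell_field, default_limits):
        _, image, _ = cell_field
        ms = rq.measure_cells(image, default_limits)
        for m in ms:
            assert m.length_px >= m.width_px
            assert m.hull_ratio >= 1.0
            assert m.area > 0
            assert 0.0 <= m.angle < 180.0

    def test_rotating_the_image_preserves_lengths(self, cell_field, default_limits):
        _, image, _ = cell_field
        a = rq.measure_cells(image, default_limits)
        b = rq.measure_cells(np.rot90(image), default_limits)
        assert len(a) == len(b)
        la = np.sort([m.length_px for m in a])
        lb = np.sort([m.length_px for m in b])
        np.testing.assert_allclose(la, lb, rtol=0.02)

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            rq.DetectionLimits(min_area=100, max_area=50)
        with pytest.raises(ValueError):
            rq.DetectionLimits(min_area=1, max_area=2, min_elongation=0.5)
        with pytest.raises(ValueError):
            rq.DetectionLimits(min_area=1, max_area=2, max_complexity=0.9)
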