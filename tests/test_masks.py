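"""Target rasterization: disc masks, Gaussian densities, box labels."""

import math

import numpy as np
import pytest

from spikelet.annotations import Point2D, PointAnnotationSet, ScaleCalibration
from spikelet.extraction import boxes_to_centers
from spikelet.masks import (
    DEFAULT_BOX_SIDE_MM,
    DEFAULT_DISC_RADIUS_MM,
    export_yolo_labels,
    load_mask_png,
    make_binary_mask,
    make_box_labels,
    make_gaussian_mask,
    save_mask_png,
)
from conftest import random_annotation_set


def brute_force_disc_mask(ann: PointAnnotationSet, radius_mm: float) -> np.ndarray:
    """Per-pixel distance scan: the definitional oracle for disc masks."""
    h, w = ann.image_size
    radius_px = ann.scale.mm_to_px(radius_mm)
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            for p in ann.points:
                if (r - p.y) ** 2 + (c - p.x) ** 2 <= radius_px**2:
                    out[r, c] = 1
                    break
    return out


class TestBinaryMask:
    def test_no_points_gives_all_zero(self):
        ann = PointAnnotationSet("z", (32, 32), [], ScaleCalibration(5.0))
        assert make_binary_mask(ann).raster.sum() == 0

    def test_single_disc_matches_brute_force_pixel_scan(self):
        ann = PointAnnotationSet(
            "one", (200, 200), [Point2D(100.0, 100.0)], ScaleCalibration(10.0)
        )
        mask = make_binary_mask(ann, radius_mm=2.0)
        oracle = brute_force_disc_mask(ann, 2.0)
        assert np.array_equal(mask.raster, oracle)
        assert mask.raster.sum() == oracle.sum() > 0

    def test_matches_brute_force_on_random_point_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            ann = random_annotation_set(rng, size=(48, 48))
            radius = float(rng.uniform(0.5, 4.0))
            assert np.array_equal(
                make_binary_mask(ann, radius).raster, brute_force_disc_mask(ann, radius)
            )

    def test_default_radius_is_two_mm(self):
        ann = PointAnnotationSet("d", (64, 64), [Point2D(32, 32)], ScaleCalibration(4.0))
        assert make_binary_mask(ann).radius_mm == DEFAULT_DISC_RADIUS_MM == 2.0

    def test_vanishing_disc_still_marks_nearest_pixel(self):
        ann = PointAnnotationSet("t", (16, 16), [Point2D(5.5, 5.5)], ScaleCalibration(0.1))
        with pytest.warns(UserWarning, match="nearest pixel"):
            mask = make_binary_mask(ann, radius_mm=0.5)  # 0.05 px radius
        assert mask.raster.sum() == 1

    def test_invalid_radius_rejected(self, simple_annotations):
        with pytest.raises(ValueError):
            make_binary_mask(simple_annotations, radius_mm=0.0)


class TestGaussianMask:
    def test_normalized_sums_to_one_with_argmax_at_point(self):
        ann = PointAnnotationSet("g", (64, 64), [Point2D(20.3, 41.8)], ScaleCalibration(4.0))
        mask = make_gaussian_mask(ann, sigma_mm=1.0, normalize=True)
        assert mask.raster.sum() == pytest.approx(1.0, abs=1e-6)
        r, c = np.unravel_index(mask.raster.argmax(), mask.raster.shape)
        assert (c, r) == (round(20.3), round(41.8))

    def test_two_identical_points_double_the_kernel(self):
        scale = ScaleCalibration(4.0)
        one = PointAnnotationSet("1", (64, 64), [Point2D(30, 30)], scale)
        two = PointAnnotationSet("2", (64, 64), [Point2D(30, 30)] * 2, scale)
        m1 = make_gaussian_mask(one, 1.0, normalize=False).raster
        m2 = make_gaussian_mask(two, 1.0, normalize=False).raster
        assert np.allclose(m2, 2.0 * m1)

    def test_kernel_ratio_at_one_sigma_is_exp_minus_half(self):
        # sigma = 20 px; the pixel 20 px from the center must sit at
        # exp(-0.5) of the peak
        ann = PointAnnotationSet("s", (201, 201), [Point2D(100, 100)], ScaleCalibration(1.0))
        m = make_gaussian_mask(ann, sigma_mm=20.0, normalize=False).raster
        assert m[100, 120] / m[100, 100] == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_normalized_sum_invariant_to_point_count(self):
        rng = np.random.default_rng(3)
        for n in (1, 4, 9):
            ann = random_annotation_set(rng, n_points=n, size=(64, 64), px_per_mm=4.0)
            total = make_gaussian_mask(ann, 1.0, normalize=True).raster.sum()
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_translation_equivariance_for_integer_shifts(self):
        scale = ScaleCalibration(4.0)
        pts = [Point2D(20, 24), Point2D(30, 40)]
        base = PointAnnotationSet("a", (96, 96), pts, scale)
        shifted = PointAnnotationSet(
            "b", (96, 96), [Point2D(p.x + 7, p.y + 5) for p in pts], scale
        )
        ma = make_gaussian_mask(base, 1.0, normalize=False).raster
        mb = make_gaussian_mask(shifted, 1.0, normalize=False).raster
        # compare away from borders where truncation windows are complete
        assert np.allclose(ma[:-5, :-7], mb[5:, 7:], atol=1e-12)

    def test_zero_points_normalized_returns_uniform_with_warning(self):
        ann = PointAnnotationSet("u", (8, 16), [], ScaleCalibration(2.0))
        with pytest.warns(UserWarning, match="uniform"):
            m = make_gaussian_mask(ann, 1.0, normalize=True)
        assert np.allclose(m.raster, 1.0 / (8 * 16))


class TestBoxLabels:
    def test_one_box_per_point_centered_in_order(self, simple_annotations):
        boxes = make_box_labels(simple_annotations, side_mm=6.0)
        assert len(boxes) == 2
        assert [b.center for b in boxes.boxes] == simple_annotations.points
        assert boxes.boxes[0].side_px == 60.0  # 6 mm at 10 px/mm
        assert DEFAULT_BOX_SIDE_MM == 6.0

    def test_corner_box_is_clipped_but_center_preserved(self):
        ann = PointAnnotationSet("c", (100, 100), [Point2D(0, 0)], ScaleCalibration(10.0))
        boxes = make_box_labels(ann, side_mm=6.0)
        b = boxes.boxes[0]
        assert b.clipped and b.center == Point2D(0, 0)
        assert b.extent((100, 100)) == (0.0, 0.0, 30.0, 30.0)

    def test_yolo_export_line_is_hand_normalized(self, tmp_path):
        ann = PointAnnotationSet("y", (200, 200), [Point2D(100, 50)], ScaleCalibration(10.0))
        boxes = make_box_labels(ann, side_mm=6.0)  # 60 px side
        f = tmp_path / "y.txt"
        export_yolo_labels(boxes, f)
        assert f.read_text() == "0 0.500000 0.250000 0.300000 0.300000\n"

    def test_empty_box_set_exports_empty_file(self, tmp_path):
        ann = PointAnnotationSet("e", (50, 50), [], ScaleCalibration(5.0))
        f = tmp_path / "e.txt"
        export_yolo_labels(make_box_labels(ann), f)
        assert f.read_text() == ""

    def test_export_round_trip_recovers_centers(self, tmp_path):
        rng = np.random.default_rng(9)
        ann = random_annotation_set(rng, n_points=5, size=(160, 120), px_per_mm=4.0)
        # keep boxes unclipped so exported extents are symmetric
        ann.points = [Point2D(p.x * 0.5 + 40, p.y * 0.5 + 40) for p in ann.points]
        f = tmp_path / "rt.txt"
        export_yolo_labels(make_box_labels(ann, side_mm=6.0), f)
        centers = boxes_to_centers(f, image_size=(160, 120))
        for got, want in zip(centers, ann.points):
            assert got.x == pytest.approx(want.x, abs=1.2e-3)
            assert got.y == pytest.approx(want.y, abs=1.2e-3)


class TestMaskPngRoundTrip:
    def test_binary_png_round_trips_exactly(self, tmp_path, simple_annotations):
        mask = make_binary_mask(simple_annotations)
        f = tmp_path / "m.png"
        save_mask_png(mask, f)
        assert np.array_equal(load_mask_png(f).raster, mask.raster)

    def test_density_png_round_trips_through_sidecar(self, tmp_path, simple_annotations):
        mask = make_gaussian_mask(simple_annotations, 1.0, normalize=True)
        f = tmp_path / "d.png"
        save_mask_png(mask, f)
        back = load_mask_png(f)
        assert back.normalized and back.sigma_mm == 1.0
        assert np.allclose(back.raster, mask.raster, atol=mask.raster.max() / 65000)
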