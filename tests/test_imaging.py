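import numpy as np
import pytest
from scipy import ndimage as ndi

from metasel.imaging import (
    equalize,
    orient_vertical,
    otsu_threshold,
    principal_angle_deg,
    segment,
    to_gray,
)
from metasel.synthgen import SynthSpec, render_spread

from conftest import as_segmented, tilted_bar_mask


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent oracle: exhaustive search over all 256 thresholds."""
    v = img.ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in range(256):
        lo = v[v <= t]
        hi = v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / v.size
        var = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestToGray:
    def test_gray_passthrough(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        np.testing.assert_array_equal(to_gray(img), img)

    def test_white_rgb(self):
        rgb = np.full((2, 2, 3), 255, dtype=np.uint8)
        assert (to_gray(rgb) == 255).all()

    def test_luminance_weighting(self):
        # round(0.299*100 + 0.587*200 + 0.114*50) = round(153.1) = 153
        px = np.array([[[100, 200, 50]]], dtype=np.uint8)
        assert to_gray(px)[0, 0] == 153

    def test_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            to_gray(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            to_gray(np.zeros(5))


class TestEqualize:
    def test_constant_maps_to_255(self):
        img = np.full((4, 4), 7, dtype=np.uint8)
        assert (equalize(img) == 255).all()

    def test_hand_computed_2x2(self):
        img = np.array([[0, 85], [170, 255]], dtype=np.uint8)
        expected = np.array([[64, 128], [191, 255]])
        np.testing.assert_array_equal(equalize(img), expected)

    def test_uniform_input_stays_near_uniform(self):
        img = np.tile(np.arange(256, dtype=np.uint8), 4).reshape(32, 32)
        out = equalize(img)
        counts = np.bincount(out.ravel(), minlength=256)
        assert counts.max() <= 2 * 4  # input has 4 pixels per level

    def test_cdf_monotone_and_endpoints(self, rng):
        img = rng.integers(0, 256, size=(50, 50)).astype(np.uint8)
        out = equalize(img)
        # the level mapping is monotone in input intensity
        order = np.argsort(img.ravel(), kind="stable")
        assert (np.diff(out.ravel()[order].astype(int)) >= 0).all()
        assert out.max() == 255


class TestOtsu:
    def test_two_delta_tie_break(self):
        img = np.array([[10] * 8, [200] * 8], dtype=np.uint8)
        assert otsu_threshold(img) == 10

    def test_bimodal_matches_brute_force(self, rng):
        a = rng.normal(60, 10, 600)
        b = rng.normal(180, 12, 400)
        img = np.clip(np.concatenate([a, b]), 0, 255).astype(np.uint8).reshape(25, 40)
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_oracle_equivalence_random_images(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            if np.unique(img).size < 2:
                continue
            assert otsu_threshold(img) == brute_force_otsu(img)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="separable"):
            otsu_threshold(np.full((5, 5), 42, dtype=np.uint8))


class TestSegment:
    def test_single_rectangle(self):
        img = np.full((30, 30), 255, dtype=np.uint8)
        img[5:15, 10:14] = 0
        objs = segment(img, min_object_px=20)
        assert len(objs) == 1
        obj = objs[0]
        assert obj.pixel_count == 40
        assert obj.mask.shape == (10, 4)
        assert obj.bbox_origin == (5, 10)
        assert obj.mask.all()
        assert not obj.touches_border

    def test_size_filter_drops_small(self):
        img = np.full((40, 40), 255, dtype=np.uint8)
        for r, c in [(2, 2), (20, 20), (30, 5)]:
            img[r:r + 3, c:c + 3] = 0
        assert segment(img, min_object_px=20) == []
        assert len(segment(img, min_object_px=9)) == 3

    def test_raster_order_ids(self):
        img = np.full((40, 40), 255, dtype=np.uint8)
        img[20:26, 2:8] = 0    # lower-left
        img[2:8, 30:36] = 0    # upper-right
        objs = segment(img, min_object_px=20)
        assert [o.bbox_origin for o in objs] == [(2, 30), (20, 2)]
        assert [o.object_id for o in objs] == [1, 2]

    def test_synthetic_spread_count_matches_ground_truth(self):
        img, gt = render_spread(SynthSpec(seed=7))
        objs = segment(equalize(img), min_object_px=10)
        assert len(objs) == len(gt)

    def test_foreground_darker_than_background(self):
        img, _ = render_spread(SynthSpec(seed=11))
        t = otsu_threshold(img)
        fg = img <= t
        assert img[fg].mean() < img[~fg].mean()

    def test_constant_image_propagates_error(self):
        with pytest.raises(ValueError):
            segment(np.full((5, 5), 9, dtype=np.uint8))


def sweep_angle_oracle(mask: np.ndarray) -> float:
    """Brute-force the rotation maximizing bounding-box height/width."""
    best_angle, best_ratio = 0.0, -1.0
    for angle in np.arange(-89.5, 90.0, 0.5):
        rot = ndi.rotate(mask.astype(np.uint8), angle, order=0, reshape=True) > 0
        ys, xs = np.nonzero(rot)
        ratio = (ys.max() - ys.min() + 1) / (xs.max() - xs.min() + 1)
        if ratio > best_ratio:
            best_ratio, best_angle = ratio, angle
    return best_angle


class TestOrientVertical:
    def test_already_vertical(self):
        mask = np.ones((40, 8), dtype=bool)
        out = orient_vertical(as_segmented(mask))
        assert abs(out.rotation_deg) < 1.0
        assert out.mask.shape == (40, 8)
        assert out.pixel_count == 320

    def test_horizontal_rectangle_rotates_90(self):
        mask = np.ones((8, 40), dtype=bool)
        out = orient_vertical(as_segmented(mask))
        h, w = out.mask.shape
        assert h > w
        assert abs(h - 40) <= 2 and abs(w - 8) <= 2
        assert abs(out.pixel_count - 320) / 320 <= 0.05

    @pytest.mark.parametrize("angle", [30.0, -30.0, 60.0])
    def test_angle_recovery_vs_sweep_oracle(self, angle):
        mask = tilted_bar_mask(angle)
        oracle = sweep_angle_oracle(mask)
        out = orient_vertical(as_segmented(mask))
        assert abs(out.rotation_deg - oracle) <= 2.0
        assert abs(abs(out.rotation_deg) - abs(angle)) <= 2.0

    def test_contraction_toward_vertical(self, rng):
        for _ in range(5):
            angle = rng.uniform(-80, 80)
            mask = tilted_bar_mask(angle, length=50, width=7)
            once = orient_vertical(as_segmented(mask))
            twice = orient_vertical(as_segmented(once.mask))
            assert abs(twice.rotation_deg) <= 2.0

    def test_no_major_axis_keeps_rotation_zero(self):
        out = orient_vertical(as_segmented(np.ones((9, 9), dtype=bool)))
        assert out.rotation_deg == 0.0

    def test_rejects_tiny_masks(self):
        with pytest.raises(ValueError):
            orient_vertical(as_segmented(np.ones((1, 2), dtype=bool)))

    def test_principal_angle_empty_mask_errors(self):
        with pytest.raises(ValueError):
            principal_angle_deg(np.zeros((3, 3), dtype=bool))
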