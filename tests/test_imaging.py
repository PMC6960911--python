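"""Color conversions, Otsu thresholding, labeling and inner rectangles."""

import numpy as np
import pytest

from orchardseg.imaging import (
    HSIImage,
    hsi_to_rgb,
    label_regions,
    max_inner_rectangle,
    otsu_threshold,
    remove_small_components,
    rgb_to_hsi,
    rgb_to_lab,
)


def brute_force_otsu(values, bins=256):
    """Independent oracle: scan every histogram bin edge for the split with
    maximal between-class variance (smallest edge on ties)."""
    vals = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_var = None, -1.0
    for k in range(1, bins):
        w0, w1 = p[:k].sum(), p[k:].sum()
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (p[:k] * centers[:k]).sum() / w0
            mu1 = (p[k:] * centers[k:]).sum() / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_k = var, k
    return edges[best_k]


def brute_force_max_rect(mask):
    """O(H^2 W^2) enumeration of all all-foreground rectangles."""
    h, w = mask.shape
    best = (0, (0, 0, 0, 0))
    for top in range(h):
        for left in range(w):
            if not mask[top, left]:
                continue
            max_right = w
            for bottom in range(top + 1, h + 1):
                row = mask[bottom - 1, left:max_right]
                run = int(np.argmin(row)) if not row.all() else len(row)
                max_right = min(max_right, left + run)
                if max_right <= left:
                    break
                area = (bottom - top) * (max_right - left)
                if area > best[0]:
                    best = (area, (top, left, bottom, max_right))
    return best


class TestHsi:
    @pytest.mark.parametrize(
        "rgb, expected_hsi",
        [
            ((0.5, 0.5, 0.5), (0.0, 0.0, 0.5)),  # achromatic
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),  # black, degenerate convention
            ((0.0, 1.0, 0.0), (2 * np.pi / 3, 1.0, 1 / 3)),  # pure green, by hand
            ((0.0, 0.0, 1.0), (4 * np.pi / 3, 1.0, 1 / 3)),  # pure blue, B>G branch
        ],
    )
    def test_forward_examples(self, rgb, expected_hsi):
        hsi = rgb_to_hsi(np.array(rgb).reshape(1, 1, 3))
        got = (hsi.hue[0, 0], hsi.sat[0, 0], hsi.intensity[0, 0])
        assert got == pytest.approx(expected_hsi, abs=1e-12)

    def test_inverse_examples(self):
        rgb = hsi_to_rgb(
            HSIImage(np.array([[2 * np.pi / 3]]), np.array([[1.0]]), np.array([[1 / 3]]))
        )
        assert rgb[0, 0] == pytest.approx([0.0, 1.0, 0.0], abs=1e-9)
        gray = hsi_to_rgb(HSIImage(np.zeros((1, 1)), np.zeros((1, 1)), np.full((1, 1), 0.3)))
        assert gray[0, 0] == pytest.approx([0.3, 0.3, 0.3], abs=1e-12)

    def test_round_trip_10000_random_pixels(self, rng):
        img = rng.random((100, 100, 3))
        back = hsi_to_rgb(rgb_to_hsi(img))
        assert np.abs(back - img).max() < 1e-6


class TestLab:
    def test_reference_points(self):
        # a*/b* at gray points only as close to 0 as the tabulated D65 white
        white = rgb_to_lab(np.ones((1, 1, 3)))
        assert white[0, 0] == pytest.approx([100.0, 0.0, 0.0], abs=1e-2)
        black = rgb_to_lab(np.zeros((1, 1, 3)))
        assert black[0, 0] == pytest.approx([0.0, 0.0, 0.0], abs=1e-2)
        # mid gray: achromatic, L from the closed-form sRGB -> Lab transform
        gray = rgb_to_lab(np.full((1, 1, 3), 0.5))
        y = ((0.5 + 0.055) / 1.055) ** 2.4  # linearized sRGB = Y for gray
        expected_l = 116.0 * y ** (1 / 3) - 16.0
        assert gray[0, 0, 0] == pytest.approx(expected_l, abs=1e-3)
        assert gray[0, 0, 1:] == pytest.approx([0.0, 0.0], abs=1e-2)


class TestOtsu:
    def test_two_group_separation(self):
        vals = np.array([0.1] * 8 + [0.9] * 8)
        thr = otsu_threshold(vals)
        assert 0.1 < thr < 0.9
        assert np.array_equal(vals > thr, vals == 0.9)

    def test_matches_brute_force_on_1000_random_histograms(self, rng):
        for _ in range(1000):
            n = rng.integers(10, 200)
            # bimodal-ish mixture
            a = rng.normal(rng.uniform(0, 0.4), rng.uniform(0.01, 0.2), n)
            b = rng.normal(rng.uniform(0.5, 1.0), rng.uniform(0.01, 0.2), n)
            vals = np.concatenate([a, b])
            assert otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals), abs=0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full(100, 0.3))


class TestLabelRegions:
    def test_counting_and_area_ratio(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:13, 10:13] = True
        mask[50:53, 50:53] = True
        rs = label_regions(mask)
        assert rs.count == 2
        assert rs.area_ratio == pytest.approx(0.18)

    def test_full_foreground(self):
        rs = label_regions(np.ones((10, 10), dtype=bool))
        assert rs.count == 1 and rs.area_ratio == 100.0

    def test_diagonal_touch_is_one_region(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert label_regions(mask).count == 1

    def test_areas_sum_to_foreground(self, rng):
        mask = rng.random((50, 50)) > 0.6
        rs = label_regions(mask)
        assert sum(r.area for r in rs.regions) == int(mask.sum())

    def test_empty_mask(self):
        rs = label_regions(np.zeros((5, 5), dtype=bool))
        assert rs.count == 0 and rs.area_ratio == 0.0

    def test_remove_small_components_threshold_exact(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:2, 0:2] = True  # area 4
        mask[10:13, 10:13] = True  # area 9
        out = remove_small_components(mask, 5)
        assert out.sum() == 9


class TestMaxInnerRectangle:
    def test_solid_square(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:11, 1:11] = True
        assert max_inner_rectangle(mask) == (1, 1, 11, 11)

    def test_l_shape(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[0:5, 0:10] = True  # horizontal arm 5x10
        mask[0:10, 0:5] = True  # vertical arm 10x5
        top, left, bottom, right = max_inner_rectangle(mask)
        assert (bottom - top) * (right - left) == 50

    def test_disk_matches_brute_force(self):
        yy, xx = np.mgrid[0:19, 0:19]
        mask = (yy - 9) ** 2 + (xx - 9) ** 2 <= 8**2
        area, _ = brute_force_max_rect(mask)
        top, left, bottom, right = max_inner_rectangle(mask)
        assert (bottom - top) * (right - left) == area

    def test_random_masks_match_brute_force(self, rng):
        for _ in range(30):
            mask = rng.random((rng.integers(3, 20), rng.integers(3, 20))) > 0.4
            if not mask.any():
                continue
            area, _ = brute_force_max_rect(mask)
            top, left, bottom, right = max_inner_rectangle(mask)
            assert (bottom - top) * (right - left) == area
            assert mask[top:bottom, left:right].all()

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            max_inner_rectangle(np.zeros((4, 4), dtype=bool))
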