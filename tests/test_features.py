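"""Region descriptors: color moments, GLCM statistics, uniform LBP."""

import numpy as np
import pytest

from orchardseg.features import (
    FEATURE_NAMES,
    FeatureVector,
    UnFeaturizableRegion,
    color_features,
    glcm_features,
    lbp_codes,
    lbp_histogram,
    quantize_gray,
    region_feature_vector,
)


def brute_force_glcm_stats(patch, levels=16, offsets=((0, 1), (1, 1), (1, 0), (1, -1))):
    """Oracle: enumerate symmetric co-occurring pixel pairs one by one and
    evaluate the five statistics from their definitions."""
    q = quantize_gray(patch, levels).astype(int)
    h, w = q.shape
    g = np.zeros((levels, levels))
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    g[q[r, c], q[r2, c2]] += 1
                    g[q[r2, c2], q[r, c]] += 1  # symmetric
    g /= g.sum()
    con = sum(
        (i - j) ** 2 * g[i, j] for i in range(levels) for j in range(levels)
    )
    asm = (g**2).sum()
    ent = -sum(
        g[i, j] * np.log10(g[i, j])
        for i in range(levels)
        for j in range(levels)
        if g[i, j] > 0
    )
    idm = sum(
        g[i, j] / (1 + (i - j) ** 2) for i in range(levels) for j in range(levels)
    )
    pi = g.sum(axis=1)
    pj = g.sum(axis=0)
    ui = sum(i * pi[i] for i in range(levels))
    vj = sum(j * pj[j] for j in range(levels))
    si = np.sqrt(sum((i - ui) ** 2 * pi[i] for i in range(levels)))
    sj = np.sqrt(sum((j - vj) ** 2 * pj[j] for j in range(levels)))
    if si * sj > 0:
        cor = (
            sum(i * j * g[i, j] for i in range(levels) for j in range(levels))
            - ui * vj
        ) / (si * sj)
    else:
        cor = 0.0
    return np.array([con, asm, ent, idm, cor])


def brute_force_lbp_histogram(patch):
    """Oracle: per-pixel loop with explicit bilinear sampling of the 8
    radius-1 neighbors and explicit uniformity counting."""
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape

    def sample(r, c):
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        fr, fc = r - r0, c - c0
        return (
            patch[r0, c0] * (1 - fr) * (1 - fc)
            + patch[r0, c0 + 1] * (1 - fr) * fc
            + patch[r0 + 1, c0] * fr * (1 - fc)
            + patch[r0 + 1, c0 + 1] * fr * fc
        )

    uniform_codes = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        if sum(bits[k] != bits[(k + 1) % 8] for k in range(8)) <= 2:
            uniform_codes.append(code)
    bin_of = {code: i for i, code in enumerate(sorted(uniform_codes))}

    hist = np.zeros(59)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for k in range(8):
                dy = np.sin(2 * np.pi * k / 8)
                dx = np.cos(2 * np.pi * k / 8)
                if abs(dy - round(dy)) < 1e-9 and abs(dx - round(dx)) < 1e-9:
                    v = patch[r + round(dy), c + round(dx)]
                else:
                    v = sample(r + dy, c + dx)
                if v >= patch[r, c] - 1e-12:
                    code |= 1 << k
            hist[bin_of.get(code, 58)] += 1
    return hist / hist.sum()


class TestColorFeatures:
    def test_uniform_region(self):
        img = np.full((5, 5, 3), [0.1, 0.6, 0.2])
        mask = np.ones((5, 5), dtype=bool)
        f = color_features(img, mask)
        assert f[0] == pytest.approx(0.1)  # mean R
        assert f[2] == pytest.approx(0.6)  # mean G
        assert f[4] == pytest.approx(0.2)  # mean B
        # all variances vanish on a uniform region
        assert f[1::2] == pytest.approx(np.zeros(7), abs=1e-12)

    def test_two_pixel_population_variance(self):
        img = np.zeros((1, 2, 3))
        img[0, 0] = [0.2, 0.5, 0.5]
        img[0, 1] = [0.4, 0.5, 0.5]
        f = color_features(img, np.ones((1, 2), dtype=bool))
        assert f[0] == pytest.approx(0.3)
        assert f[1] == pytest.approx(0.01)  # population variance

    def test_hue_wraparound_uses_circular_mean(self):
        # two saturated pixels with hues just either side of 0/2pi: the
        # circular mean is ~0, the linear mean would be ~pi
        img = np.zeros((1, 2, 3))
        img[0, 0] = [1.0, 0.1, 0.0]  # hue slightly above 0
        img[0, 1] = [1.0, 0.0, 0.1]  # hue slightly below 2*pi
        f = color_features(img, np.ones((1, 2), dtype=bool))
        h_mean = f[6]
        assert min(h_mean, 2 * np.pi - h_mean) < 0.2
        assert f[7] < 0.1  # circular variance small for nearby hues

    def test_single_pixel_raises(self):
        img = np.zeros((2, 2, 3))
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(UnFeaturizableRegion):
            color_features(img, mask)


class TestGlcm:
    def test_constant_patch_conventions(self):
        f = glcm_features(np.full((6, 6), 0.4))
        con, asm, ent, idm, cor = f
        assert con == 0.0
        assert asm == 1.0
        assert ent == 0.0
        assert idm == 1.0
        assert cor == 0.0  # zero marginal variance -> 0 by convention

    def test_alternating_strip_horizontal(self):
        # [0,1,0,1,...] columns: every horizontal pair differs by one level
        patch = np.tile(np.array([0.0, 1.0] * 4), (2, 1))
        con, asm, ent, idm, cor = glcm_features(patch, levels=2, angles=(0.0,))
        assert con == pytest.approx(1.0)
        assert idm == pytest.approx(0.5)

    def test_matches_brute_force_on_random_patches(self, rng):
        for _ in range(50):
            patch = rng.random((8, 8))
            np.testing.assert_allclose(
                glcm_features(patch), brute_force_glcm_stats(patch), atol=1e-10
            )

    def test_too_small_raises(self):
        with pytest.raises(UnFeaturizableRegion):
            glcm_features(np.zeros((1, 5)))


class TestLbp:
    def test_constant_patch_single_uniform_bin(self):
        hist = lbp_histogram(np.full((6, 6), 0.3))
        # ties count as >=, so a flat patch gives the all-ones pattern 255,
        # the last uniform code
        assert hist.sum() == pytest.approx(1.0)
        assert hist[57] == pytest.approx(1.0)

    def test_gray_shift_invariance_exact(self, rng):
        patch = rng.random((10, 10))
        np.testing.assert_array_equal(
            lbp_codes(patch), lbp_codes(patch + 0.2)
        )

    def test_positive_affine_invariance(self, rng):
        patch = rng.random((10, 10))
        np.testing.assert_array_equal(
            lbp_histogram(patch), lbp_histogram(0.5 * patch + 0.1)
        )

    def test_matches_brute_force_on_random_patches(self, rng):
        for _ in range(50):
            patch = rng.random((8, 8))
            np.testing.assert_allclose(
                lbp_histogram(patch), brute_force_lbp_histogram(patch), atol=1e-10
            )

    def test_histogram_sums_to_one(self, rng):
        assert lbp_histogram(rng.random((9, 9))).sum() == pytest.approx(1.0)

    def test_too_small_raises(self):
        with pytest.raises(UnFeaturizableRegion):
            lbp_histogram(np.zeros((2, 5)))


class TestRegionFeatureVector:
    def test_vector_length_and_names(self, rng):
        img = rng.random((20, 20, 3))
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 4:16] = True
        fv = region_feature_vector(img, mask)
        assert fv.values.shape == (78,)
        assert len(FEATURE_NAMES) == 78
        assert FeatureVector.N_COLOR + FeatureVector.N_GLCM + FeatureVector.N_LBP == 78

    def test_full_mask_mode_uses_whole_rectangle(self, rng):
        # on a rectangular mask the two modes agree: the inner rectangle of a
        # rectangle is itself
        img = rng.random((16, 16, 3))
        mask = np.ones((16, 16), dtype=bool)
        a = region_feature_vector(img, mask, mode="full_mask")
        b = region_feature_vector(img, mask, mode="inner_rect")
        np.testing.assert_array_equal(a.values, b.values)

    def test_texture_window_is_inner_rectangle(self, rng):
        # an L-shaped region's texture must come from the largest inner
        # rectangle, not the bounding box
        img = rng.random((20, 20, 3))
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:5, 0:18] = True
        mask[0:18, 0:5] = True
        fv = region_feature_vector(img, mask)
        from orchardseg.features import glcm_features as gf, lbp_histogram as lh
        from orchardseg.imaging import max_inner_rectangle

        top, left, bottom, right = max_inner_rectangle(mask)
        window = img.mean(axis=-1)[top:bottom, left:right]
        np.testing.assert_array_equal(fv.values[14:19], gf(window))
        np.testing.assert_array_equal(fv.values[19:], lh(window))

    def test_thin_region_excluded(self, rng):
        img = rng.random((10, 10, 3))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, 4] = True  # 1 px wide
        with pytest.raises(UnFeaturizableRegion):
            region_feature_vector(img, mask)

    def test_mask_permutation_invariance(self, rng):
        # featurization must not depend on any pixel ordering; rerun twice
        img = rng.random((15, 15, 3))
        mask = np.zeros((15, 15), dtype=bool)
        mask[3:12, 3:12] = True
        a = region_feature_vector(img, mask)
        b = region_feature_vector(img.copy(order="F"), np.array(mask, order="F"))
        np.testing.assert_array_equal(a.values, b.values)
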