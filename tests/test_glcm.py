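"""GLCM: brute-force oracle equivalence, analytic correlation cases, decay."""

import numpy as np
import pytest

from fibrilquant import (
    GLCMConfig,
    RoiMask,
    SHGImage,
    correlation_decay,
    generate_fiber_scene,
    glcm,
    glcm_correlation,
    quantize,
)
from fibrilquant.errors import DegenerateTextureError, NoPairsError

from conftest import small_spec

_OFF = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_brute_force(levels, d, angle, symmetric, n, roi=None):
    """Independent oracle: explicit double loop over all pixel pairs."""
    dr, dc = (o * d for o in _OFF[angle])
    h, w = levels.shape
    counts = np.zeros((n, n))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                if roi is not None and not (roi[r, c] and roi[r2, c2]):
                    continue
                counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise NoPairsError("no pairs")
    return counts / total


class TestQuantize:
    def test_constant_image_maps_to_level_zero(self):
        img = SHGImage(np.full((5, 5), 3.3), 1.0)
        assert np.array_equal(quantize(img, 8), np.zeros((5, 5), dtype=int))

    def test_two_level_split_at_midpoint(self):
        img = SHGImage(np.array([[0.0, 0.4], [0.5, 1.0]]), 1.0)
        assert np.array_equal(quantize(img, 2), np.array([[0, 0], [1, 1]]))

    def test_integer_ramp_is_fixed_point(self):
        img = SHGImage(np.array([[0.0, 1.0, 2.0, 3.0]]), 1.0)
        assert np.array_equal(quantize(img, 4), np.array([[0, 1, 2, 3]]))


class TestGlcmOracle:
    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("d", [1, 2, 3])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_on_random_small_images(self, angle, d, symmetric):
        rng = np.random.default_rng(100 * d + angle)
        for shape in ((8, 8), (16, 16), (5, 16)):
            levels = rng.integers(0, 6, size=shape)
            got = glcm(levels, d, angle, symmetric=symmetric, n_gray_levels=6)
            want = glcm_brute_force(levels, d, angle, symmetric, 6)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_brute_force_with_roi(self):
        rng = np.random.default_rng(9)
        levels = rng.integers(0, 4, size=(12, 12))
        roi = rng.random((12, 12)) < 0.6
        roi_mask = RoiMask(roi)
        for angle in (0, 45, 90, 135):
            got = glcm(levels, 2, angle, True, roi=roi_mask, n_gray_levels=4)
            want = glcm_brute_force(levels, 2, angle, True, 4, roi=roi)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_skimage_where_conventions_coincide(self):
        # independent library cross-check: symmetric GLCM at 0/90 deg
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(3)
        levels = rng.integers(0, 8, size=(20, 20))
        for d, angle, sk_angle in ((1, 0, 0.0), (2, 0, 0.0), (1, 90, np.pi / 2)):
            ours = glcm(levels, d, angle, symmetric=True, n_gray_levels=8)
            sk = graycomatrix(
                levels.astype(np.uint8), [d], [sk_angle], levels=8,
                symmetric=True, normed=True,
            )[:, :, 0, 0]
            np.testing.assert_allclose(ours, sk, atol=1e-12)

    def test_alternating_row_pairs(self):
        # 1x4 image [0,1,0,1]: three horizontal pairs, symmetrized
        P = glcm(np.array([[0, 1, 0, 1]]), 1, 0, symmetric=True, n_gray_levels=2)
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_concentrates_at_origin(self):
        P = glcm(np.zeros((6, 6), dtype=int), 1, 0, n_gray_levels=3)
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_normalization_and_symmetry_invariants(self):
        rng = np.random.default_rng(17)
        levels = rng.integers(0, 5, size=(15, 13))
        for angle in (0, 45, 90, 135):
            P = glcm(levels, 2, angle, symmetric=True, n_gray_levels=5)
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_array_equal(P, P.T)

    def test_offset_beyond_extent_rejected(self):
        with pytest.raises(NoPairsError):
            glcm(np.zeros((4, 4), dtype=int), 5, 0, n_gray_levels=2)


class TestCorrelation:
    def test_checkerboard_is_perfectly_anticorrelated(self):
        rr, cc = np.mgrid[0:8, 0:8]
        board = ((rr + cc) % 2).astype(int)
        P = glcm(board, 1, 0, symmetric=True, n_gray_levels=2)
        assert glcm_correlation(P) == pytest.approx(-1.0, abs=1e-12)

    def test_period_two_stripes_at_matching_offset_correlate_perfectly(self):
        stripes = np.tile(np.array([0, 1]), (8, 4)).astype(int)
        P = glcm(stripes, 2, 0, symmetric=True, n_gray_levels=2)
        assert glcm_correlation(P) == pytest.approx(1.0, abs=1e-12)

    def test_constant_texture_is_degenerate(self):
        P = glcm(np.zeros((6, 6), dtype=int), 1, 0, n_gray_levels=2)
        with pytest.raises(DegenerateTextureError):
            glcm_correlation(P)

    def test_correlation_bounded_on_random_textures(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            levels = rng.integers(0, 6, size=(12, 12))
            P = glcm(levels, 1, 45, symmetric=True, n_gray_levels=6)
            assert -1.0 - 1e-12 <= glcm_correlation(P) <= 1.0 + 1e-12


class TestDecay:
    def test_white_noise_has_no_spatial_correlation(self):
        spec = small_spec(
            n_fibers=0, noise_poisson_scale=0.0, noise_gaussian_sd=20.0,
            background_level=100.0, seed=1,
        )
        scene = generate_fiber_scene(spec)
        dec = correlation_decay(
            scene.image, GLCMConfig(distances_px=tuple(range(1, 17)))
        )
        assert max(abs(c) for c in dec.correlation) < 0.1

    def test_single_distance_auc_is_that_correlation(self, aligned_scene):
        dec = correlation_decay(aligned_scene.image, GLCMConfig(distances_px=(1,)))
        assert dec.auc == dec.correlation[0]

    def test_half_decay_interpolates_first_crossing(self):
        from fibrilquant.glcm import _half_decay

        d = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([0.8, 0.6, 0.2, 0.1])
        # crosses 0.4 between d=2 and d=3: 2 + (0.6-0.4)/(0.6-0.2)
        assert _half_decay(d, c) == pytest.approx(2.5)
        assert _half_decay(d, np.array([0.8, 0.7, 0.6, 0.5])) == np.inf

    def test_constant_image_propagates_named_degeneracy(self):
        img = SHGImage(np.full((32, 32), 5.0), 1.0, name="flat")
        with pytest.raises(DegenerateTextureError, match="flat"):
            correlation_decay(img, GLCMConfig(distances_px=(1, 2)))
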