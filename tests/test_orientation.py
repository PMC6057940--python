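"""Structure-tensor orientation: gradient exactness, conventions, recovery."""

import numpy as np
import pytest

from fibrilquant import (
    SHGImage,
    axial_distance_deg,
    bspline_gradient,
    compare_orientation_distributions,
    generate_fiber_scene,
    normalize_intensity,
    orientation_analysis,
    orientation_field,
    orientation_histogram,
    structure_tensor,
    wrap_axial_deg,
)
from fibrilquant.errors import ImageTooSmallError, NoOrientedSignalError
from fibrilquant.orientation import OrientationField

from conftest import small_spec

# mirror-boundary prefilter influence decays as |sqrt(3)-2|^depth; 14 px
# suffices for 1e-6 absolute error at O(1)-scaled polynomial coefficients
_DEPTH = 14


def _interior(a, depth=_DEPTH):
    return a[depth:-depth, depth:-depth]


class TestBsplineGradient:
    def test_linear_ramp_derivative_is_exact(self):
        r, c = np.mgrid[0:32, 0:32].astype(float)
        fx, fy = bspline_gradient(SHGImage(3 * c, 1.0))
        assert np.allclose(_interior(fx), 3.0, atol=1e-6)
        assert np.allclose(fy, 0.0, atol=1e-10)

    def test_constant_image_has_zero_gradient(self):
        fx, fy = bspline_gradient(SHGImage(np.full((16, 16), 5.0), 1.0))
        assert np.allclose(fx, 0.0, atol=1e-12) and np.allclose(fy, 0.0, atol=1e-12)

    def test_quadratic_reproduced_exactly_in_interior(self):
        r, c = np.mgrid[0:32, 0:32].astype(float)
        fx, _ = bspline_gradient(SHGImage(c**2, 1.0))
        err = np.abs(_interior(fx) - _interior(2 * c))
        assert err.max() < 1e-6

    def test_cubic_polynomial_derivatives_exact_in_interior(self):
        r, c = np.mgrid[0:48, 0:48].astype(float)
        r, c = r / 47.0, c / 47.0  # O(1) coefficients
        img = c**3 - 0.5 * r**3 + r * c + 0.25 * c**2
        fx_true = 3 * c**2 + r + 0.5 * c
        fy_true = -1.5 * r**2 + c
        fx, fy = bspline_gradient(SHGImage(img + 2.0, 1.0))
        assert np.abs(_interior(fx) - _interior(fx_true) / 47.0).max() < 1e-6
        assert np.abs(_interior(fy) - _interior(fy_true) / 47.0).max() < 1e-6

    def test_too_small_image_rejected(self):
        with pytest.raises(ImageTooSmallError):
            bspline_gradient(SHGImage(np.ones((3, 3)), 1.0))


class TestStructureTensor:
    def test_constant_gradient_averages_to_itself(self):
        fx = np.ones((20, 20))
        fy = np.zeros((20, 20))
        Jxx, Jxy, Jyy = structure_tensor(fx, fy, 2.0)
        assert np.allclose(Jxx, 1.0) and np.allclose(Jxy, 0.0) and np.allclose(Jyy, 0.0)

    def test_zero_gradient_gives_zero_tensor(self):
        z = np.zeros((10, 10))
        assert all(np.allclose(t, 0) for t in structure_tensor(z, z, 1.5))

    def test_vertical_stripes_dominated_by_column_gradient(self):
        r, c = np.mgrid[0:64, 0:64].astype(float)
        img = np.sin(2 * np.pi * c / 8) + 1.0
        fx, fy = bspline_gradient(SHGImage(img, 1.0))
        Jxx, Jxy, Jyy = structure_tensor(fx, fy, 2.0)
        inner = slice(10, -10)
        assert np.abs(Jxy[inner, inner]).max() < 1e-3
        assert Jxx[inner, inner].min() > 10 * Jyy[inner, inner].max()

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        fx, fy = rng.standard_normal((2, 30, 30))
        Jxx, Jxy, Jyy = structure_tensor(fx, fy, 2.0)
        assert (Jxx >= 0).all() and (Jyy >= 0).all()
        assert (Jxx * Jyy - Jxy**2 >= -1e-9).all()


class TestOrientationField:
    def _field_for(self, img):
        fx, fy = bspline_gradient(SHGImage(img, 1.0))
        J = structure_tensor(fx, fy, 2.0)
        return orientation_field(*J, border_exclude_px=6)

    def test_vertical_stripes_read_ninety_degrees(self):
        _, c = np.mgrid[0:64, 0:64].astype(float)
        f = self._field_for(np.sin(2 * np.pi * c / 8) + 1)
        assert abs(np.median(f.theta_deg[f.valid_mask])) == 90.0

    def test_horizontal_stripes_read_zero_degrees(self):
        r, _ = np.mgrid[0:64, 0:64].astype(float)
        f = self._field_for(np.sin(2 * np.pi * r / 8) + 1)
        assert np.median(np.abs(f.theta_deg[f.valid_mask])) < 1e-6

    def test_diagonal_pattern_reads_forty_five(self):
        r, c = np.mgrid[0:64, 0:64].astype(float)
        f = self._field_for(np.sin(2 * np.pi * (r + c) / 8) + 1)
        med = np.median(f.theta_deg[f.valid_mask])
        assert axial_distance_deg(med, 45.0) < 1.0

    def test_theta_in_axial_range_and_coherency_bounded(self, aligned_scene):
        field, _ = orientation_analysis(aligned_scene.image)
        assert (field.theta_deg > -90).all() and (field.theta_deg <= 90).all()
        assert (field.coherency >= 0).all() and (field.coherency <= 1).all()

    def test_white_noise_is_incoherent_and_flat(self):
        spec = small_spec(
            n_fibers=0, noise_poisson_scale=0.0, noise_gaussian_sd=20.0,
            background_level=100.0, seed=42,
        )
        scene = generate_fiber_scene(spec)
        field, hist = orientation_analysis(scene.image, coherency_gate=0.0)
        assert np.median(field.coherency[field.valid_mask]) < 0.3
        assert hist.frequency.max() < 3.0 / hist.frequency.size


class TestOrientationHistogram:
    def _degenerate_field(self, theta_value):
        shape = (20, 20)
        return OrientationField(
            theta_deg=np.full(shape, theta_value),
            coherency=np.ones(shape),
            energy=np.ones(shape),
            valid_mask=np.ones(shape, dtype=bool),
        )

    def test_single_angle_field_peaks_there_with_full_alignment(self):
        h = orientation_histogram(self._degenerate_field(30.0), delta_deg=10.0)
        assert abs(h.peak_angle_deg - 30.0) <= 0.5
        assert h.alignment_frequency == 1.0

    def test_uniform_field_alignment_near_uniform_expectation(self):
        rng = np.random.default_rng(5)
        shape = (200, 200)
        field = OrientationField(
            theta_deg=wrap_axial_deg(rng.uniform(-90, 90, shape)),
            coherency=np.ones(shape),
            energy=np.ones(shape),
            valid_mask=np.ones(shape, dtype=bool),
        )
        h = orientation_histogram(field, delta_deg=10.0, weighting="none")
        assert h.alignment_frequency == pytest.approx(20.0 / 180.0, abs=0.02)

    def test_mass_conservation_and_window_dominates_peak_bin(self, aligned_scene):
        _, h = orientation_analysis(aligned_scene.image)
        assert h.frequency.sum() == pytest.approx(1.0, abs=1e-9)
        assert h.alignment_frequency >= h.frequency.max()

    def test_empty_valid_mask_is_named_error(self):
        field = self._degenerate_field(0.0)
        object.__setattr__(field, "valid_mask", np.zeros((20, 20), dtype=bool))
        with pytest.raises(NoOrientedSignalError):
            orientation_histogram(field)

    def test_bin_width_must_divide_180(self):
        with pytest.raises(ValueError):
            orientation_histogram(self._degenerate_field(0.0), bin_width_deg=7.0)


class TestParameterRecovery:
    def test_peak_recovered_on_dense_phantoms(self):
        # dense matrix: many independent fibers stabilize the histogram mode
        errs = []
        for seed in range(10):
            spec = small_spec(
                n_fibers=1500, fiber_length_um=30.0, peak_angle_deg=40.0,
                kappa=8.0, seed=seed,
            )
            scene = generate_fiber_scene(spec)
            _, h = orientation_analysis(
                normalize_intensity(scene.image, "percentile(99.9)")
            )
            errs.append(axial_distance_deg(h.peak_angle_deg, 40.0))
        assert np.mean(errs) <= 2.0

    def test_alignment_frequency_tracks_truth_on_sparse_phantoms(self):
        # sparse scenes: window averaging across crossing fibers is rare, so
        # the measured alignment frequency is an unbiased read of the truth
        diffs = []
        for seed in range(10):
            spec = small_spec(
                height_px=512, width_px=512, pixel_size_um=0.625,
                n_fibers=250, fiber_length_um=40.0, peak_angle_deg=40.0,
                kappa=8.0, seed=seed,
            )
            scene = generate_fiber_scene(spec)
            _, h = orientation_analysis(
                normalize_intensity(scene.image, "percentile(99.9)")
            )
            diffs.append(h.alignment_frequency - scene.true_alignment_fraction)
        assert abs(np.mean(diffs)) <= 0.05


class TestDistributionComparison:
    @staticmethod
    def _axial_sample(rng, n, kappa, peak=0.0):
        if kappa > 0:
            return wrap_axial_deg(
                np.degrees(rng.vonmises(np.radians(2 * peak), kappa, n)) / 2
            )
        return wrap_axial_deg(rng.uniform(-90, 90, n))

    def test_identical_samples_do_not_differ(self):
        rng = np.random.default_rng(0)
        s = self._axial_sample(rng, 500, 5.0)
        _, p = compare_orientation_distributions(s, s)
        assert p > 0.99

    def test_concentrated_vs_uniform_is_detected(self):
        rng = np.random.default_rng(1)
        a = self._axial_sample(rng, 1000, 0.0)
        b = self._axial_sample(rng, 1000, 20.0, peak=25.0)
        _, p = compare_orientation_distributions(a, b)
        assert p < 1e-3

    def test_type_one_error_calibrated_under_uniform_null(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = self._axial_sample(rng, 1000, 0.0)
            b = self._axial_sample(rng, 1000, 0.0)
            _, p = compare_orientation_distributions(a, b)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(NoOrientedSignalError):
            compare_orientation_distributions([], [1.0])
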