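"""Reflectance correction, ROI extraction, MSC, Savitzky-Golay, derivative."""

import numpy as np
import pytest

import frostspec as fs
from frostspec.preprocess import (
    PreprocessError,
    SegmentationError,
    derivative_vector,
    extract_roi_mean,
)
from frostspec.simulate import SpectralCube, SpectrumMatrix


def _matrix(values, wavelengths=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    wl = np.arange(values.shape[1], dtype=float) if wavelengths is None else wavelengths
    return SpectrumMatrix(values, np.asarray(wl, dtype=float),
                          [f"s{i}" for i in range(values.shape[0])])


class TestReflectanceCorrection:
    def test_white_and_dark_identities(self):
        D = np.full((4, 5), 0.1)
        W = np.full((4, 5), 0.9)
        np.testing.assert_allclose(fs.reflectance_correction(W, D, W), 1.0)
        np.testing.assert_allclose(fs.reflectance_correction(D, D, W), 0.0)

    def test_scalar_hand_example(self):
        assert fs.reflectance_correction(
            np.array([[0.6]]), np.array([[0.1]]), np.array([[0.9]])
        )[0, 0] == pytest.approx(0.625)

    def test_affine_invariance(self, rng):
        R = rng.uniform(0.2, 0.8, (6, 10))
        D = rng.uniform(0.0, 0.1, (6, 10))
        W = rng.uniform(0.9, 1.0, (6, 10))
        base = fs.reflectance_correction(R, D, W)
        shifted = fs.reflectance_correction(3.2 * R + 0.7, 3.2 * D + 0.7, 3.2 * W + 0.7)
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_zero_denominator_names_position(self):
        D = np.zeros((2, 3))
        W = np.ones((2, 3))
        W[1, 2] = 0.0
        with pytest.raises(PreprocessError, match=r"\(1, 2\)"):
            fs.reflectance_correction(np.ones((2, 3)), D, W)

    def test_optional_clipping(self):
        C = fs.reflectance_correction(
            np.array([[1.2]]), np.array([[0.0]]), np.array([[1.0]]), clip=True
        )
        assert C[0, 0] == 1.0


class TestROI:
    def test_uniform_cube_returns_constant_spectrum(self):
        spectrum = np.linspace(0.3, 0.5, 8)
        cube = fs.simulate_cube(spectrum, (10, 10), pixel_noise_sd=0.0)
        mean, mask = extract_roi_mean(cube)
        np.testing.assert_allclose(mean, spectrum, atol=1e-12)
        np.testing.assert_array_equal(mask, cube.leaf_mask)

    def test_two_region_cube_recovers_the_bright_region(self):
        B = 6
        values = np.full((4, 4, B), 0.05)
        leaf = np.linspace(0.4, 0.6, B)
        values[:2] = leaf
        cube = SpectralCube(values, np.arange(B, dtype=float),
                            np.zeros((4, 4), dtype=bool))
        mean, mask = extract_roi_mean(cube, threshold=0.2)
        np.testing.assert_allclose(mean, leaf, atol=1e-12)
        assert mask.sum() == 8

    def test_stacked_rois_form_variables_by_samples_matrix(self):
        B, n = 176, 192
        wl = fs.GeneratorConfig().wavelengths()
        rng = np.random.default_rng(0)
        columns = []
        for _ in range(n):
            spectrum = rng.uniform(0.3, 0.6, B)
            cube = fs.simulate_cube(spectrum, (6, 6), pixel_noise_sd=0.0,
                                    wavelengths=wl)
            mean, _ = extract_roi_mean(cube)
            columns.append(mean)
        matrix = np.column_stack(columns)
        assert matrix.shape == (176, 192)

    def test_empty_mask_raises(self):
        cube = SpectralCube(np.full((3, 3, 4), 0.2), np.arange(4.0),
                            np.ones((3, 3), dtype=bool))
        with pytest.raises(SegmentationError):
            extract_roi_mean(cube, threshold=0.9)


class TestMSC:
    def test_reference_spectrum_is_unchanged(self):
        ref = np.sin(np.linspace(0, 3, 30)) + 2
        out = fs.msc(_matrix(ref), reference=ref)
        np.testing.assert_allclose(out.values[0], ref, atol=1e-10)

    def test_affine_distortion_is_inverted_exactly(self):
        ref = np.sin(np.linspace(0, 3, 30)) + 2
        out = fs.msc(_matrix(2.0 * ref + 3.0), reference=ref)
        np.testing.assert_allclose(out.values[0], ref, atol=1e-10)

    def test_random_affine_family_collapses_to_the_base_spectrum(self, rng):
        base = np.cos(np.linspace(0, 4, 50)) + 2
        rows = np.stack([rng.uniform(0.5, 2) * base + rng.uniform(-1, 1)
                         for _ in range(12)])
        out = fs.msc(_matrix(rows), reference=base)
        assert np.ptp(out.values, axis=0).max() < 1e-10

    def test_idempotent(self, rng):
        X = _matrix(rng.uniform(0.2, 0.8, (8, 40)))
        ref = X.values.mean(axis=0)
        once = fs.msc(X, reference=ref)
        twice = fs.msc(once, reference=ref)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_constant_reference_and_degenerate_spectrum_errors(self):
        with pytest.raises(PreprocessError, match="constant"):
            fs.msc(_matrix(np.ones(10)), reference=np.ones(10))
        ref = np.linspace(0, 1, 10)
        with pytest.raises(PreprocessError, match="slope"):
            fs.msc(_matrix(np.ones(10)), reference=ref)


def _sg_oracle(y, window, polyorder):
    """Brute-force local least-squares fit evaluated at each interior point."""
    half = window // 2
    out = np.full(y.size, np.nan)
    x = np.arange(-half, half + 1, dtype=float)
    for i in range(half, y.size - half):
        coeffs = np.polynomial.polynomial.polyfit(x, y[i - half : i + half + 1], polyorder)
        out[i] = coeffs[0]
    return out


class TestSavitzkyGolay:
    def test_polynomial_inputs_are_reproduced(self):
        x = np.linspace(0, 1, 60)
        y = 0.3 + 1.2 * x - 0.8 * x**2
        out = fs.savitzky_golay(_matrix(y), window=11, polyorder=2)
        np.testing.assert_allclose(out.values[0], y, atol=1e-10)

    def test_matches_per_window_least_squares_oracle(self, rng):
        y = rng.normal(size=41)
        for window, order in [(5, 2), (9, 3), (11, 2)]:
            out = fs.savitzky_golay(_matrix(y), window, order).values[0]
            oracle = _sg_oracle(y, window, order)
            interior = ~np.isnan(oracle)
            np.testing.assert_allclose(out[interior], oracle[interior], atol=1e-8)

    def test_full_order_filter_is_identity_at_interior_points(self, rng):
        y = rng.normal(size=30)
        out = fs.savitzky_golay(_matrix(y), window=5, polyorder=4).values[0]
        np.testing.assert_allclose(out[2:-2], y[2:-2], atol=1e-8)

    def test_smoothing_reduces_noise_variance(self, rng):
        y = rng.normal(size=(5, 200))
        out = fs.savitzky_golay(_matrix(y), window=11, polyorder=2)
        assert out.values.var() < y.var()

    def test_window_validation(self):
        with pytest.raises(PreprocessError):
            fs.savitzky_golay(_matrix(np.arange(30.0)), window=8, polyorder=2)
        with pytest.raises(PreprocessError):
            fs.savitzky_golay(_matrix(np.arange(5.0)), window=11, polyorder=2)


class TestFirstDerivative:
    def test_constant_and_linear_inputs(self):
        wl = np.arange(10, dtype=float) * 2.0
        const = fs.first_derivative(_matrix(np.full(10, 3.3), wl))
        np.testing.assert_allclose(const.values, 0.0, atol=1e-14)
        line = fs.first_derivative(_matrix(0.7 * wl, wl))
        np.testing.assert_allclose(line.values, 0.7, atol=1e-12)

    def test_hand_example(self):
        out = derivative_vector(np.array([0.2, 0.5, 0.4]), dx=3.5)
        np.testing.assert_allclose(out, [0.3 / 3.5, -0.1 / 3.5])

    def test_linearity(self, rng):
        y, z = rng.normal(size=20), rng.normal(size=20)
        lhs = derivative_vector(2.0 * y + 3.0 * z, 1.7)
        rhs = 2.0 * derivative_vector(y, 1.7) + 3.0 * derivative_vector(z, 1.7)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_output_length_and_midpoint_axis(self):
        wl = np.linspace(400, 500, 11)
        out = fs.first_derivative(_matrix(np.arange(11.0), wl))
        assert out.values.shape[1] == 10
        np.testing.assert_allclose(out.wavelengths, (wl[:-1] + wl[1:]) / 2)

    def test_too_short_input(self):
        with pytest.raises(PreprocessError):
            derivative_vector(np.array([1.0]), 1.0)


class TestChain:
    def test_chain_equals_stage_composition(self, rng):
        X = _matrix(rng.uniform(0.2, 0.8, (6, 50)),
                    np.linspace(400, 900, 50))
        config = fs.PreprocessConfig(sg_window=7, sg_polyorder=2)
        chained = fs.preprocess_chain(X, config)
        staged = fs.first_derivative(
            fs.savitzky_golay(fs.msc(X), 7, 2)
        )
        np.testing.assert_allclose(chained.values, staged.values, atol=1e-12)
        assert chained.values.shape[1] == X.values.shape[1] - 1

    def test_chain_shrinks_between_replicate_scatter(self, rng):
        base = 0.4 + 0.2 * np.sin(np.linspace(0, 5, 80))
        reps = np.stack([rng.uniform(0.7, 1.3) * base + rng.uniform(-0.05, 0.05)
                         for _ in range(20)])
        X = _matrix(reps, np.linspace(400, 900, 80))
        pre = fs.preprocess_chain(X, fs.PreprocessConfig(sg_window=7))
        raw_spread = reps.std(axis=0).mean()
        pre_spread = pre.values.std(axis=0).mean()
        assert pre_spread < raw_spread
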