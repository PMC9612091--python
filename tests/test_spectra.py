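"""Chromophore spectra, Beer's-law synthesis/unmixing, and ROI statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfdikit import (ChromophoreBasis, ChromophoreMap, ChromophoreSpectrum,
                     fit_concentrations, fit_concentrations_batch,
                     load_packaged_spectrum, make_basis, resample_spectrum,
                     roi_average, synthesize_absorption)


def simple_spectrum(name="water", wl=(900.0, 910.0, 920.0), vals=(0.02, 0.04, 0.03)):
    return ChromophoreSpectrum(name, np.array(wl), np.array(vals),
                               concentration_unit="percent volume fraction")


class TestResample:
    def test_identity_on_native_grid(self):
        s = simple_spectrum()
        out = resample_spectrum(s, s.wavelengths)
        np.testing.assert_array_equal(out.unit_absorption, s.unit_absorption)

    def test_linear_midpoint(self):
        s = simple_spectrum(vals=(0.02, 0.04, 0.03))
        out = resample_spectrum(s, np.array([905.0]))
        assert out.unit_absorption[0] == pytest.approx(0.03, abs=1e-15)

    def test_coarse_then_fine_matches_direct_interpolation(self):
        """Re-resampling a coarse grid agrees with direct interpolation."""
        water = load_packaged_spectrum("water")
        coarse = resample_spectrum(water, np.arange(900.0, 1001.0, 10.0))
        fine_grid = np.arange(900.0, 1001.0, 1.0)
        via_coarse = resample_spectrum(coarse, fine_grid).unit_absorption
        # independent oracle: direct piecewise-linear interpolation
        direct = np.interp(fine_grid, coarse.wavelengths, coarse.unit_absorption)
        assert np.max(np.abs(via_coarse - direct)) < 1e-15

    def test_out_of_support_names_wavelength(self):
        with pytest.raises(ValueError, match="1500"):
            resample_spectrum(simple_spectrum(), np.array([905.0, 1500.0]))


class TestSynthesize:
    def test_zero_concentrations_give_zero_spectrum(self, basis900):
        mu_a = synthesize_absorption(basis900, np.zeros(2))
        np.testing.assert_array_equal(mu_a, 0.0)

    def test_pure_water_reproduces_water_spectrum(self, basis900):
        mu_a = synthesize_absorption(basis900, np.array([100.0, 0.0]))
        np.testing.assert_allclose(
            mu_a, basis900.spectra[0].unit_absorption, rtol=1e-14)

    def test_hand_arithmetic_mixture(self, basis900):
        """80% water + 10% lipid equals 0.8 a_w + 0.1 a_l wavelength-wise."""
        a_w = basis900.spectra[0].unit_absorption
        a_l = basis900.spectra[1].unit_absorption
        mu_a = synthesize_absorption(basis900, np.array([80.0, 10.0]))
        np.testing.assert_allclose(mu_a, 0.8 * a_w + 0.1 * a_l, rtol=1e-14)

    def test_length_mismatch_raises(self, basis900):
        with pytest.raises(ValueError, match="concentrations"):
            synthesize_absorption(basis900, np.array([1.0, 2.0, 3.0]))


class TestFit:
    def test_noiseless_round_trip_exact(self, basis900):
        truth = np.array([85.0, 15.0])
        c, resid = fit_concentrations(synthesize_absorption(basis900, truth), basis900)
        np.testing.assert_allclose(c, truth, rtol=1e-10)
        assert resid < 1e-14

    @settings(derandomize=True, max_examples=30)
    @given(water=st.floats(5.0, 95.0), lipid=st.floats(5.0, 95.0))
    def test_round_trip_property(self, basis900, water, lipid):
        truth = np.array([water, lipid])
        c, _ = fit_concentrations(synthesize_absorption(basis900, truth), basis900)
        np.testing.assert_allclose(c, truth, rtol=1e-8)

    def test_two_by_two_matches_closed_form_inverse(self):
        """Square system: fit equals the explicit 2x2 matrix inverse."""
        basis = make_basis(["water", "lipid"], np.array([930.0, 970.0]))
        E = basis.matrix
        y = np.array([0.02, 0.04])
        # oracle: Cramer's rule
        det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
        expected = np.array([
            (E[1, 1] * y[0] - E[0, 1] * y[1]) / det,
            (E[0, 0] * y[1] - E[1, 0] * y[0]) / det,
        ])
        c, resid = fit_concentrations(y, basis, nonneg=not np.all(expected >= 0))
        c2, _ = fit_concentrations(y, basis, nonneg=False)
        np.testing.assert_allclose(c2, expected, rtol=1e-10)
        assert resid < 1e-12 or not np.all(expected >= 0)

    def test_unbiased_under_gaussian_noise(self, basis900, rng):
        """Mean of repeated noisy refits stays within 3 SE of the truth."""
        truth = np.array([60.0, 40.0])
        mu_a = synthesize_absorption(basis900, truth)
        n = 10_000
        noisy = mu_a + rng.normal(0, 2e-4, (n, mu_a.size))
        c, _, _ = fit_concentrations_batch(noisy, basis900)
        se = c.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(c.mean(axis=0) - truth) < 3 * se)

    def test_scale_equivariance_unconstrained(self, basis900):
        mu_a = synthesize_absorption(basis900, np.array([50.0, 30.0]))
        c1, _ = fit_concentrations(mu_a, basis900, nonneg=False)
        c2, _ = fit_concentrations(3.0 * mu_a, basis900, nonneg=False)
        np.testing.assert_allclose(c2, 3.0 * c1, rtol=1e-10)

    def test_residual_zero_in_span_positive_off_span(self, basis900):
        mu_a = synthesize_absorption(basis900, np.array([70.0, 20.0]))
        _, r0 = fit_concentrations(mu_a, basis900)
        E = basis900.matrix
        # perturbation orthogonal to the basis column span
        q, _ = np.linalg.qr(E)
        v = np.zeros(E.shape[0])
        v[0] = 1.0
        v -= q @ (q.T @ v)
        _, r1 = fit_concentrations(mu_a + 1e-3 * v / np.linalg.norm(v), basis900)
        assert r0 < 1e-14 < r1

    def test_nan_wavelengths_masked(self, basis900):
        truth = np.array([85.0, 15.0])
        mu_a = synthesize_absorption(basis900, truth)
        mu_a[3] = np.nan
        c, _ = fit_concentrations(mu_a, basis900)
        np.testing.assert_allclose(c, truth, rtol=1e-10)

    def test_too_few_finite_wavelengths_raise(self, basis900):
        mu_a = np.full(basis900.grid.size, np.nan)
        mu_a[0] = 0.01
        with pytest.raises(ValueError, match="finite wavelengths"):
            fit_concentrations(mu_a, basis900)

    def test_rank_deficient_basis_rejected(self):
        s = simple_spectrum("water")
        dup = ChromophoreSpectrum("lipid", s.wavelengths,
                                  2.0 * s.unit_absorption,
                                  concentration_unit=s.concentration_unit)
        with pytest.raises(np.linalg.LinAlgError):
            ChromophoreBasis(s.wavelengths, (s, dup))


def _cmap(maps, pitch=0.1):
    maps = np.asarray(maps, dtype=float)
    return ChromophoreMap(("water",), ("percent volume fraction",),
                          maps[None], pixel_pitch=pitch)


class TestRoiAverage:
    def test_constant_field(self):
        rep = roi_average(_cmap(np.full((40, 40), 70.0)), (20, 20), 2.0)
        assert rep["mean"][0] == pytest.approx(70.0)
        assert rep["sd"][0] == 0.0

    def test_half_plane_matches_brute_force(self):
        img = np.where(np.arange(40) < 20, 60.0, 80.0) * np.ones((40, 1))
        center, diam, pitch = (20.0, 19.5), 3.0, 0.1
        rep = roi_average(_cmap(img, pitch), center, diam)
        # oracle: brute-force pixel enumeration
        r_px = 0.5 * diam / pitch
        total, count = 0.0, 0
        for r in range(40):
            for c in range(40):
                if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= r_px**2:
                    total += img[r, c]
                    count += 1
        assert rep["mean"][0] == pytest.approx(total / count)
        assert abs(rep["mean"][0] - 70.0) < 80.0 / count  # pixel quantization

    def test_subpixel_diameter_single_pixel(self):
        img = np.arange(100.0).reshape(10, 10)
        rep = roi_average(_cmap(img), (4, 7), 0.05)
        assert rep["mean"][0] == img[4, 7]
        assert rep["sd"][0] == 0.0
        assert rep["n_pixels"][0] == 1

    def test_nan_pixels_excluded_and_counted(self):
        img = np.full((20, 20), 50.0)
        img[10, 10] = np.nan
        rep = roi_average(_cmap(img), (10, 10), 1.0)
        assert rep["mean"][0] == pytest.approx(50.0)
        assert rep["n_nan"][0] == 1

    def test_circle_outside_image_raises(self):
        with pytest.raises(ValueError, match="outside"):
            roi_average(_cmap(np.ones((10, 10))), (5, 5), 5.0)
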