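"""Forward reflectance model, lookup-table inversion, penetration depth."""

import numpy as np
import pytest

from sfdikit import (OpticalProperties, build_lut, effective_penetration_depth,
                     invert_map, invert_pixel, load_lut, rd_forward, save_lut)
from sfdikit.optics import modulated_attenuation

# frozen from an independent scripted evaluation of the same closed forms
RD_0p02_1p0_FX0 = 0.5171879674542004
RD_0p02_1p0_FX02 = 0.11680268645418103
DEPTH_0p02_1p0_FX02 = 0.7807886627022385
DEPTH_0p02_1p0_FX0 = 4.0422604172722165


class TestForward:
    def test_frozen_regression_values(self):
        assert rd_forward(0.02, 1.0, 0.0) == pytest.approx(RD_0p02_1p0_FX0, rel=1e-12)
        assert rd_forward(0.02, 1.0, 0.2) == pytest.approx(RD_0p02_1p0_FX02, rel=1e-12)

    def test_zero_frequency_reduces_to_planar_attenuation(self):
        mu_a, mu_s = 0.03, 1.5
        mu_eff = np.sqrt(3 * mu_a * (mu_a + mu_s))
        assert modulated_attenuation(mu_a, mu_s, 0.0) == pytest.approx(mu_eff, rel=1e-14)

    def test_monotone_decreasing_in_fx(self, rng):
        mu_a = rng.uniform(0.0067, 0.082, 50)
        mu_s = rng.uniform(0.67, 4.2, 50)
        assert np.all(rd_forward(mu_a, mu_s, 0.2) < rd_forward(mu_a, mu_s, 0.0))

    def test_monotone_in_mu_a_and_mu_s(self, rng):
        """Rd falls with absorption and rises with scattering at fx=0.2."""
        mu_a = np.linspace(0.0067, 0.082, 60)
        assert np.all(np.diff(rd_forward(mu_a, 1.5, 0.2)) < 0)
        mu_s = np.linspace(0.67, 4.2, 60)
        assert np.all(np.diff(rd_forward(0.02, mu_s, 0.2)) > 0)

    def test_bounded_in_unit_interval(self, rng):
        mu_a = rng.uniform(0.001, 0.2, 200)
        mu_s = rng.uniform(0.3, 6.0, 200)
        for fx in (0.0, 0.05, 0.2, 0.4):
            rd = rd_forward(mu_a, mu_s, fx)
            assert np.all((rd > 0) & (rd < 1))

    def test_nonpositive_properties_rejected(self):
        with pytest.raises(ValueError):
            rd_forward(-0.01, 1.0, 0.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.01, 0.0)


class TestLut:
    def test_construction_matches_forward_pointwise(self):
        lut = build_lut(grid_sizes=(2, 2), fx_pair=(0.0, 0.2))
        for i, a in enumerate(lut.mu_a_grid):
            for j, s in enumerate(lut.mu_s_grid):
                assert lut.rd1[i, j] == rd_forward(a, s, 0.0)
                assert lut.rd2[i, j] == rd_forward(a, s, 0.2)

    def test_nodewise_monotonicity_along_mu_a(self):
        # over the validated property ranges; the diffusion closed form is
        # mildly non-monotone in mu_a at fx=0.2 for mu_s' < ~0.55 mm^-1,
        # which the wide default grid includes as margin
        lut = build_lut(mu_a_range=(0.0067, 0.082), mu_s_range=(0.67, 4.2),
                        grid_sizes=(50, 50))
        assert np.all(np.diff(lut.rd1, axis=0) < 0)
        assert np.all(np.diff(lut.rd2, axis=0) < 0)
        # higher frequency reflects less, node-wise
        assert np.all(lut.rd2 < lut.rd1)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="f1 == f2"):
            build_lut(fx_pair=(0.2, 0.2))

    def test_saved_table_round_trips_and_inverts_identically(self, tmp_path, lut):
        path = tmp_path / "lut.csv"
        save_lut(lut, path)
        imported = load_lut(path)
        np.testing.assert_allclose(imported.rd1, lut.rd1, rtol=1e-9)
        rd_pair = (rd_forward(0.03, 2.0, 0.0), rd_forward(0.03, 2.0, 0.2))
        p1, _ = invert_pixel(rd_pair, lut)
        p2, _ = invert_pixel(rd_pair, imported)
        assert p1.mu_a == pytest.approx(p2.mu_a, rel=1e-6)
        assert p1.mu_s_prime == pytest.approx(p2.mu_s_prime, rel=1e-6)


class TestInversion:
    def test_node_recovery(self, lut):
        a, s = lut.mu_a_grid[40], lut.mu_s_grid[70]
        props, flag = invert_pixel((lut.rd1[40, 70], lut.rd2[40, 70]), lut)
        assert not flag
        assert props.mu_a == pytest.approx(a, rel=1e-9)
        assert props.mu_s_prime == pytest.approx(s, rel=1e-9)

    def test_round_trip_sweep_within_half_percent(self, lut, rng):
        """Forward-then-invert over the validated property ranges."""
        mu_a = rng.uniform(0.0067, 0.082, 1000)
        mu_s = rng.uniform(0.67, 4.2, 1000)
        pm = invert_map(rd_forward(mu_a, mu_s, 0.0)[None],
                        rd_forward(mu_a, mu_s, 0.2)[None], lut)
        assert not pm.out_of_range.any()
        assert np.max(np.abs(pm.mu_a[0] - mu_a) / mu_a) < 5e-3
        assert np.max(np.abs(pm.mu_s_prime[0] - mu_s) / mu_s) < 5e-3

    def test_unattainable_pair_clamped_and_flagged(self, lut):
        props, flag = invert_pixel((0.99, 0.98), lut)
        assert flag
        (a_lo, a_hi), (s_lo, s_hi) = lut.bounds
        on_boundary = (props.mu_a in (a_lo, a_hi)) or \
            (props.mu_s_prime in (s_lo, s_hi)) or \
            np.isclose(props.mu_a, a_lo) or np.isclose(props.mu_s_prime, s_hi)
        assert on_boundary

    def test_reflectance_outside_unit_interval_rejected(self, lut):
        with pytest.raises(ValueError, match="reflectances"):
            invert_pixel((1.2, 0.5), lut)

    def test_uniform_map_matches_single_pixel(self, lut):
        rd_pair = (rd_forward(0.025, 1.8, 0.0), rd_forward(0.025, 1.8, 0.2))
        pm = invert_map(np.full((8, 8), rd_pair[0]), np.full((8, 8), rd_pair[1]), lut)
        single, _ = invert_pixel(rd_pair, lut)
        np.testing.assert_allclose(pm.mu_a, single.mu_a, rtol=1e-9)
        np.testing.assert_allclose(pm.mu_s_prime, single.mu_s_prime, rtol=1e-9)

    def test_two_region_scene_recovers_both_truths(self, lut):
        a = np.where(np.arange(16) < 8, 0.02, 0.05) * np.ones((8, 1))
        s = np.where(np.arange(16) < 8, 1.0, 2.5) * np.ones((8, 1))
        pm = invert_map(rd_forward(a, s, 0.0), rd_forward(a, s, 0.2), lut)
        np.testing.assert_allclose(pm.mu_a, a, rtol=5e-3)
        np.testing.assert_allclose(pm.mu_s_prime, s, rtol=5e-3)

    def test_corrupted_pixel_isolated(self, lut):
        rd1 = np.full((4, 4), rd_forward(0.02, 1.0, 0.0))
        rd2 = np.full((4, 4), rd_forward(0.02, 1.0, 0.2))
        rd1[2, 2] = 1.5  # physically impossible reflectance
        pm = invert_map(rd1, rd2, lut)
        assert pm.out_of_range[2, 2]
        assert pm.out_of_range.sum() == 1
        good = ~pm.out_of_range
        np.testing.assert_allclose(pm.mu_a[good], 0.02, rtol=1e-6)

    def test_shape_mismatch_rejected(self, lut):
        with pytest.raises(ValueError, match="share shape"):
            invert_map(np.ones((4, 4)) * 0.3, np.ones((4, 5)) * 0.1, lut)

    def test_grid_density_convergence(self, rng):
        """Doubling the table grid moves results by < 0.1% relative."""
        mu_a = rng.uniform(0.0067, 0.082, 100)
        mu_s = rng.uniform(0.67, 4.2, 100)
        rd1 = rd_forward(mu_a, mu_s, 0.0)[None]
        rd2 = rd_forward(mu_a, mu_s, 0.2)[None]
        coarse = invert_map(rd1, rd2, build_lut(grid_sizes=(128, 128)))
        fine = invert_map(rd1, rd2, build_lut(grid_sizes=(256, 256)))
        assert np.max(np.abs(coarse.mu_a - fine.mu_a) / fine.mu_a) < 1e-3
        assert np.max(np.abs(coarse.mu_s_prime - fine.mu_s_prime)
                      / fine.mu_s_prime) < 1e-3


class TestPenetrationDepth:
    def test_frozen_values(self):
        assert effective_penetration_depth(0.02, 1.0, 0.2) == pytest.approx(
            DEPTH_0p02_1p0_FX02, rel=1e-12)
        assert effective_penetration_depth(0.02, 1.0, 0.0) == pytest.approx(
            DEPTH_0p02_1p0_FX0, rel=1e-12)

    def test_strictly_decreasing_in_fx_mu_a_mu_s(self):
        assert effective_penetration_depth(0.02, 1.0, 0.4) < \
            effective_penetration_depth(0.02, 1.0, 0.2)
        assert effective_penetration_depth(0.04, 1.0, 0.2) < \
            effective_penetration_depth(0.02, 1.0, 0.2)
        assert effective_penetration_depth(0.02, 2.0, 0.2) < \
            effective_penetration_depth(0.02, 1.0, 0.2)
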