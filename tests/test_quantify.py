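"""Calibration, VOI statistics, dAVH, homogeneity index, RC / PVE correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y90voxdose import (
    PETAcqParams,
    RCTable,
    Y90,
    calibration_factor_y90,
    davh,
    emitted_positrons,
    homogeneity_index,
    percent_deviation,
    pve_correct,
    recovery_coefficients,
    simulate_pet,
    voi_stats,
)
from y90voxdose.grid import GeometryError, VOIMask

from conftest import full_mask, make_grid


class TestCalibration:
    def test_unit_branch_ratio_is_identity(self):
        assert calibration_factor_y90(3.7, 1.0) == 3.7

    def test_rescales_positron_equivalent_concentration_to_y90(self):
        # 31.86 Bq/mL positron-equivalent at BR 3.186e-5 -> 1e6 Bq/mL of 90Y
        cf = calibration_factor_y90(1.0, 3.186e-5)
        assert 31.86 * cf == pytest.approx(1.0e6, rel=1e-12)

    def test_linearity_and_domain(self):
        assert calibration_factor_y90(2.0, 0.5) == 2 * calibration_factor_y90(1.0, 0.5)
        with pytest.raises(ValueError):
            calibration_factor_y90(1.0, 0.0)


class TestVOIStats:
    def test_constant_image_collapses_all_statistics(self):
        grid = make_grid(np.full((4, 4, 4), 7.0))
        s = voi_stats(grid, full_mask(grid))
        assert (s.mean, s.q1, s.q3, s.sd, s.skewness) == (7.0, 7.0, 7.0, 0.0, 0.0)

    def test_linear_interpolation_quantiles(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0] * 16).reshape(4, 4, 4)
        s = voi_stats(make_grid(vals), full_mask(make_grid(vals)))
        assert (s.mean, s.min, s.max) == (2.5, 1.0, 4.0)
        # hand values for {1,2,3,4} under linear order-statistic interpolation
        q = voi_stats(make_grid(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)),
                      full_mask(make_grid(np.zeros((1, 1, 4)))))
        assert (q.q1, q.q3) == (1.75, 3.25)

    def test_empty_mask_and_geometry_mismatch_raise(self):
        grid = make_grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            voi_stats(grid, VOIMask(np.zeros((3, 3, 3), bool), grid.voxel_size_mm))
        with pytest.raises(GeometryError):
            voi_stats(grid, VOIMask(np.ones((4, 4, 4), bool), grid.voxel_size_mm))

    def test_low_count_poisson_voi_is_positively_skewed(self):
        grid = make_grid(np.full((12, 12, 12), 1.0e5))
        img = simulate_pet(grid, Y90, PETAcqParams(scan_time_s=900.0, psf_fwhm_mm=0.0, seed=4))
        assert voi_stats(img, full_mask(img)).skewness > 0


class TestDAVH:
    def test_constant_image_single_bin_unit_integral(self):
        grid = make_grid(np.full((4, 4, 4), 3.0))
        h = davh(grid, full_mask(grid))
        assert np.count_nonzero(h.density) == 1
        assert h.integral() == pytest.approx(1.0, abs=1e-12)

    def test_two_level_image_splits_half_and_half(self):
        vals = np.zeros((4, 4, 4))
        vals[:2] = 1.0
        vals[2:] = 3.0
        grid = make_grid(vals)
        h = davh(grid, full_mask(grid), bin_width=1.0)
        fractions = h.density * np.diff(h.bin_edges)
        assert fractions[fractions > 0] == pytest.approx([0.5, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_bins=st.integers(3, 200),
    )
    def test_integral_is_one_for_random_images(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        grid = make_grid(rng.gamma(2.0, 1e5, size=(6, 6, 6)))
        vals = grid.values
        h = davh(grid, full_mask(grid), bin_width=float(np.ptp(vals)) / n_bins)
        assert h.integral() == pytest.approx(1.0, abs=1e-9)


class TestHomogeneityIndex:
    def test_constant_image_is_zero(self):
        grid = make_grid(np.full((3, 3, 3), 5.0))
        assert homogeneity_index(grid, full_mask(grid)) == 0.0

    def test_two_voxel_hand_value(self):
        grid = make_grid(np.array([0.0, 2.0]).reshape(1, 1, 2))
        assert homogeneity_index(grid, full_mask(grid)) == pytest.approx(1.0)

    def test_scale_invariance_and_sd_over_mean_identity(self, rng):
        vals = rng.gamma(3.0, 1e5, size=(5, 5, 5))
        grid = make_grid(vals)
        mask = full_mask(grid)
        hi = homogeneity_index(grid, mask)
        assert homogeneity_index(make_grid(7.3 * vals), mask) == pytest.approx(hi, rel=1e-12)
        assert hi == pytest.approx(np.std(vals) / np.mean(vals), rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        grid = make_grid(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            homogeneity_index(grid, full_mask(grid))


class TestRecoveryAndPVE:
    def test_perfect_recovery_gives_unit_rc(self):
        t = recovery_coefficients([2.0, 2.0], 2.0, [1.0, 10.0])
        assert np.all(t.rc == 1.0)

    def test_rc_ratio_definition(self):
        table = recovery_coefficients([0.456e6, 1.96e6], 2.28e6, [0.52, 26.52])
        assert table.rc[0] == pytest.approx(0.2)

    def test_pve_correct_reproduces_reported_correction(self):
        # mean 4.30 MBq/mL at RC 0.811 -> 5.30 MBq/mL
        table = RCTable([1.0, 19.13, 100.0], [0.5, 0.811, 0.9])
        assert pve_correct(4.30, 19.13, table) == pytest.approx(5.30, abs=0.005)

    def test_pve_correct_clamps_outside_table(self):
        table = RCTable([1.0, 10.0], [0.4, 0.8])
        assert pve_correct(1.0, 0.01, table) == pytest.approx(1 / 0.4)
        assert pve_correct(1.0, 1e4, table) == pytest.approx(1 / 0.8)

    def test_correct_then_multiply_is_identity_at_tabulated_volumes(self):
        table = RCTable([0.52, 2.57, 11.49], [0.2, 0.55, 0.82])
        for v, rc in zip(table.volumes_mL, table.rc):
            assert pve_correct(1.23 * rc, v, table) == pytest.approx(1.23, rel=1e-12)

    def test_table_needs_two_rows(self):
        with pytest.raises(ValueError):
            RCTable([1.0], [0.5])


class TestDeviationAndEmissions:
    @pytest.mark.parametrize(
        "measured,true,expected,tol",
        [
            (257.0, 273.0, -5.9, 0.05),
            (5.30, 5.50, -3.6, 0.05),
            (0.19, 0.24, -20.8, 0.05),
            (19.60, 19.13, 2.45, 0.01),
            (3.3, 3.3, 0.0, 1e-12),
        ],
    )
    def test_percent_deviation_matches_reported_values(self, measured, true, expected, tol):
        assert percent_deviation(measured, true) == pytest.approx(expected, abs=tol)

    def test_percent_deviation_rejects_zero_truth(self):
        with pytest.raises(ValueError):
            percent_deviation(1.0, 0.0)

    def test_emitted_positrons_closed_form(self):
        n = emitted_positrons(5.5e6, 19.13, Y90, 900.0)
        assert n == pytest.approx(3.01e6, rel=0.005)
        # decay correction over 15 min is small but present
        undecayed = 5.5e6 * 19.13 * Y90.branch_ratio_beta_plus * 900.0
        assert 0.998 < n / undecayed < 1.0

    def test_emitted_positrons_zero_cases(self):
        assert emitted_positrons(1.0, 1.0, Y90, 0.0) == 0.0
        assert emitted_positrons(0.0, 1.0, Y90, 100.0) == 0.0
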