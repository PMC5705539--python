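"""Local deposition, kernel convolution, MIRD averaging, and dDVHs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y90voxdose import (
    NuclideConstants,
    UnitError,
    VOIMask,
    Y90,
    beta_point_kernel,
    ddvh,
    delta_kernel,
    dose_summary,
    kernel_convolve_dose,
    ld_constant,
    local_deposition_dose,
    mird_average_dose,
)
from y90voxdose.dosimetry import ML_PER_KG, DoseKernel
from y90voxdose.nuclide import MEV_TO_J

from conftest import full_mask, make_grid

VOXEL = (2.73, 2.73, 3.27)


class TestLDConstant:
    def test_matches_printed_constant(self):
        """T=2.67 d, E=0.932 MeV give ~4.966e-5 Gy s mL within 0.5% rounding."""
        assert ld_constant(Y90, rounded_factor=True) == pytest.approx(4.966e-5, rel=5e-3)
        assert ld_constant(Y90) == pytest.approx(4.966e-5, rel=5e-3)

    def test_closed_form(self):
        expected = 1.44 * Y90.half_life_s * 0.932 * MEV_TO_J * 1000.0
        assert ld_constant(Y90, rounded_factor=True) == expected
        assert ld_constant(Y90) == pytest.approx(expected * (1 / math.log(2)) / 1.44)

    def test_linear_in_half_life_and_energy(self):
        base = ld_constant(Y90)
        doubled_T = NuclideConstants(2 * Y90.half_life_s, 0.932, 2.28, 3.186e-5)
        doubled_E = NuclideConstants(Y90.half_life_s, 2 * 0.932, 2.28, 3.186e-5)
        assert ld_constant(doubled_T) == pytest.approx(2 * base, rel=1e-12)
        assert ld_constant(doubled_E) == pytest.approx(2 * base, rel=1e-12)


class TestLocalDeposition:
    def test_uniform_megabecquerel_dose(self):
        grid = make_grid(np.full((4, 4, 4), 1.0e6))
        dose = local_deposition_dose(grid, Y90)
        assert np.all(dose.values == pytest.approx(49.7, rel=0.005))
        assert dose.unit == "Gy"

    def test_zero_in_zero_out_and_unit_guard(self):
        grid = make_grid(np.zeros((3, 3, 3)))
        assert np.all(local_deposition_dose(grid, Y90).values == 0.0)
        with pytest.raises(UnitError):
            local_deposition_dose(make_grid(np.ones((2, 2, 2)), unit="counts"), Y90)

    def test_total_energy_conservation(self, rng):
        """Sum(D * m_voxel) equals (1/lambda) * E_mean * sum(A0) exactly."""
        grid = make_grid(rng.uniform(0, 1e6, size=(5, 5, 5)))
        dose = local_deposition_dose(grid, Y90)
        m_voxel_kg = grid.voxel_volume_mL / ML_PER_KG
        energy = np.sum(dose.values) * m_voxel_kg
        a0_total = np.sum(grid.values) * grid.voxel_volume_mL
        expected = a0_total / Y90.decay_constant * Y90.mean_beta_energy_J()
        assert energy == pytest.approx(expected, rel=1e-12)

    def test_negative_voxels_are_clamped(self):
        vals = np.full((3, 3, 3), 1e5)
        vals[0, 0, 0] = -50.0
        dose = local_deposition_dose(make_grid(vals), Y90)
        assert dose.values[0, 0, 0] == 0.0


class TestKernelConvolution:
    def test_delta_kernel_reproduces_local_deposition(self, rng):
        grid = make_grid(rng.uniform(0, 1e6, size=(6, 6, 6)))
        ld = local_deposition_dose(grid, Y90)
        conv = kernel_convolve_dose(grid, delta_kernel(Y90, VOXEL), Y90)
        assert conv.values == pytest.approx(ld.values, rel=1e-9)

    def test_delta_kernel_vs_rounded_constant_within_0p3_percent(self, rng):
        grid = make_grid(rng.uniform(1e3, 1e6, size=(4, 4, 4)))
        ld44 = local_deposition_dose(grid, Y90, rounded_factor=True)
        conv = kernel_convolve_dose(grid, delta_kernel(Y90, VOXEL), Y90)
        assert np.max(np.abs(conv.values / ld44.values - 1)) < 3e-3

    def test_single_hot_voxel_energy_conservation(self):
        """Total map energy equals cumulated decays x mean energy, minus leakage."""
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 2.0e6
        grid = make_grid(vals)
        kernel = beta_point_kernel(Y90, VOXEL)
        dose = kernel_convolve_dose(grid, kernel, Y90)
        m_voxel_kg = grid.voxel_volume_mL / ML_PER_KG
        energy = np.sum(dose.values) * m_voxel_kg
        cumulated = 2.0e6 * grid.voxel_volume_mL / Y90.decay_constant
        expected = cumulated * Y90.mean_beta_energy_J() * (1 - kernel.leakage)
        assert energy == pytest.approx(expected, rel=1e-6)

    def test_kernel_energy_closure_within_declared_leakage(self):
        kernel = beta_point_kernel(Y90, VOXEL)
        assert kernel.leakage <= 0.005
        assert kernel.energy_per_decay_J() == pytest.approx(
            Y90.mean_beta_energy_J() * (1 - kernel.leakage), rel=1e-9
        )

    def test_radiation_equilibrium_uniform_activity(self):
        """LD, MIRD and interior kernel dose coincide on uniform activity."""
        conc = 5.5e6
        grid = make_grid(np.full((24, 24, 24), conc))
        kernel = beta_point_kernel(Y90, VOXEL)
        conv = kernel_convolve_dose(grid, kernel, Y90)
        ld = local_deposition_dose(grid, Y90)
        mird = mird_average_dose(conc, Y90)
        center = ld.values[12, 12, 12]
        assert mird == pytest.approx(center, rel=1e-12)
        assert conv.values[12, 12, 12] == pytest.approx(center, rel=2 * kernel.leakage + 1e-9)

    def test_voxel_size_mismatch_rejected(self):
        grid = make_grid(np.ones((4, 4, 4)))
        kernel = delta_kernel(Y90, (2.0, 2.0, 2.0))
        from y90voxdose import GeometryError

        with pytest.raises(GeometryError):
            kernel_convolve_dose(grid, kernel, Y90)

    def test_kernel_validation(self):
        with pytest.raises(Exception):
            DoseKernel(np.zeros((2, 3, 3)), VOXEL)  # even dimension
        with pytest.raises(ValueError):
            DoseKernel(np.zeros((3, 3, 3)), VOXEL)  # S(0) == 0


class TestMIRD:
    def test_reported_day1_scale(self):
        assert mird_average_dose(5.5e6, Y90, rounded_factor=True) == pytest.approx(273, rel=0.005)

    def test_zero_and_negative(self):
        assert mird_average_dose(0.0, Y90) == 0.0
        with pytest.raises(ValueError):
            mird_average_dose(-1.0, Y90)

    def test_equals_mean_ld_on_uniform_image(self):
        grid = make_grid(np.full((5, 5, 5), 7.7e5))
        ld = local_deposition_dose(grid, Y90)
        mean, _ = dose_summary(ld, full_mask(grid))
        assert mird_average_dose(7.7e5, Y90) == pytest.approx(mean, rel=1e-12)


class TestDVH:
    def test_constant_dose_single_bin(self):
        dose = make_grid(np.full((4, 4, 4), 50.0), unit="Gy")
        mask = full_mask(dose)
        h = ddvh(dose, mask, bin_width=2.0)
        assert np.count_nonzero(h.dv_per_dD) == 1
        assert h.dv_per_dD.max() == pytest.approx(mask.volume_mL / 2.0)

    def test_integral_equals_mask_volume_exactly(self, rng):
        dose = make_grid(rng.gamma(2.0, 30.0, size=(8, 8, 8)), unit="Gy")
        mask = full_mask(dose)
        h = ddvh(dose, mask)
        assert h.volume_mL == mask.volume_mL  # bit-exact accumulated volume
        assert h.integral_mL() == pytest.approx(mask.volume_mL, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1), n_bins=st.integers(5, 150))
    def test_integral_property_random_maps(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        dose = make_grid(rng.uniform(0, 120.0, size=(6, 6, 6)), unit="Gy")
        mask = full_mask(dose)
        bw = float(np.ptp(dose.values)) / n_bins
        h = ddvh(dose, mask, bin_width=bw)
        assert h.volume_mL == mask.volume_mL
        assert h.integral_mL() == pytest.approx(mask.volume_mL, rel=1e-9)

    def test_mean_dose_from_dvh_within_half_bin(self, rng):
        dose = make_grid(rng.uniform(10, 90, size=(8, 8, 8)), unit="Gy")
        mask = full_mask(dose)
        bw = 2.0
        h = ddvh(dose, mask, bin_width=bw)
        assert abs(h.mean_dose_Gy() - np.mean(dose.values)) <= bw / 2

    def test_dose_summary_population_sd(self):
        dose = make_grid(np.array([0.0, 2.0]).reshape(1, 1, 2), unit="Gy")
        mean, sd = dose_summary(dose, full_mask(dose))
        assert (mean, sd) == (1.0, 1.0)

    def test_ld_dose_cv_equals_activity_hi(self, insert_phantom):
        """LD scales activity voxel-wise, so dose CV == activity HI."""
        from y90voxdose import PETAcqParams, homogeneity_index, simulate_pet

        _, activity, masks = insert_phantom
        img = simulate_pet(activity, Y90, PETAcqParams(scan_time_s=900.0, psf_fwhm_mm=6.0, seed=9))
        ld = local_deposition_dose(img, Y90)
        mean, sd = dose_summary(ld, masks["insert"])
        hi = homogeneity_index(img, masks["insert"])
        assert sd / mean == pytest.approx(hi, rel=1e-9)
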