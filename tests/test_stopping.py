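"""Stopping power, ranges, degrader transport and the straggled ELF curve."""

import warnings

import numpy as np
import pytest

from braggfricke.materials import (
    CARBON,
    PMMA,
    PROTON,
    SUPER_FRICKE,
    WATER,
    BeamSpec,
    MaterialStack,
)
from braggfricke.stopping import (
    DepthProfile,
    LowEnergyDomainError,
    bragg_elf_curve,
    csda_range,
    degrade_energy,
    dose_rate_profile,
    mass_stopping_power,
)

from conftest import carbon_beam, proton_beam


class TestMassStoppingPower:
    def test_64_mev_proton_in_water_magnitude(self):
        # independent hand evaluation of the Bethe formula with I = 75 eV
        assert mass_stopping_power(64.0, WATER, PROTON) == pytest.approx(
            9.60, rel=0.10
        )

    def test_decreasing_with_energy_in_bethe_regime(self):
        energies = np.array([1.0, 5.0, 25.0, 64.0, 100.0])
        s = mass_stopping_power(energies, WATER, PROTON)
        assert np.all(np.diff(s) < 0)
        assert np.all(s > 0)

    def test_z_squared_scaling_at_equal_velocity(self):
        # same beta <=> same kinetic energy per unit rest mass
        e_p = 25.0
        e_c = e_p * CARBON.rest_mass / PROTON.rest_mass
        ratio = mass_stopping_power(e_c, WATER, CARBON) / mass_stopping_power(
            e_p, WATER, PROTON
        )
        # z^2 = 36 with a small deviation from the Tmax mass terms
        assert ratio == pytest.approx(36.0, rel=0.02)

    def test_low_energy_cutoff_raises(self):
        with pytest.raises(LowEnergyDomainError):
            mass_stopping_power(0.3, WATER, PROTON)
        with pytest.raises(LowEnergyDomainError):
            mass_stopping_power(4.0, WATER, CARBON)  # < 0.5 MeV/u * 12


class TestCsdaRange:
    def test_25_mev_proton_in_water(self):
        # brute-force 1-keV trapezoid of the oracle stopping power gives 6.2 mm
        assert csda_range(25.0, WATER, PROTON) == pytest.approx(6.2, rel=0.10)

    def test_strictly_increasing_in_energy(self):
        r = [csda_range(e, WATER, PROTON) for e in (5.0, 10.0, 25.0, 64.0)]
        assert np.all(np.diff(r) > 0)

    def test_vanishes_at_cutoff(self):
        assert csda_range(0.5001, WATER, PROTON) < 1e-3

    def test_matches_fine_trapezoid_oracle(self):
        # independent integration of 1/S at 1 keV steps
        e = np.arange(0.5001, 25.0, 1e-3)
        s = mass_stopping_power(e, WATER, PROTON)
        oracle_mm = np.trapezoid(1.0 / s, e) * 10.0  # rho = 1
        assert csda_range(25.0, WATER, PROTON) == pytest.approx(
            oracle_mm, rel=1e-3
        )


class TestDegradeEnergy:
    def test_zero_thickness_is_identity(self):
        assert degrade_energy(64.0, (PMMA, 0.0), PROTON) == 64.0

    def test_proton_beamline_degrader(self):
        # 64 MeV -> nominal 25 MeV through 23.57 mm PMMA
        out = degrade_energy(64.0, (PMMA, 23.57), PROTON)
        assert out == pytest.approx(25.0, rel=0.10)

    def test_carbon_beamline_degrader(self):
        # 1.14 GeV carbon -> ~550 MeV through 14 mm PMMA
        out = degrade_energy(1140.0, (PMMA, 14.0), CARBON)
        assert out == pytest.approx(550.0, rel=0.10)

    def test_strictly_decreasing_with_thickness(self):
        outs = [degrade_energy(64.0, (PMMA, t), PROTON) for t in (5.0, 10.0, 20.0)]
        assert np.all(np.diff(outs) < 0)

    def test_stopping_inside_layer_warns_not_raises(self):
        with pytest.warns(UserWarning, match="stops inside"):
            out = degrade_energy(10.0, (PMMA, 50.0), PROTON)
        assert out == 0.0


class TestBraggElfCurve:
    def test_energy_conservation(self, proton_profile, carbon_profile):
        for dp in (proton_profile, carbon_profile):
            e_in = dp.metadata["energy_at_sample_MeV"]
            assert dp.integral() == pytest.approx(e_in, rel=0.01)

    def test_peak_near_csda_range(self, proton_profile):
        e_in = proton_profile.metadata["energy_at_sample_MeV"]
        r = csda_range(e_in, SUPER_FRICKE, PROTON)
        sigma = proton_profile.metadata["sigma_mm"]
        assert abs(proton_profile.peak_depth() - r) <= 2 * sigma

    def test_sigma_free_curve_matches_naive_stepping_oracle(self, proton_stack):
        beam = BeamSpec(PROTON, 64.0, 0.0, 1e-9, 8.0)
        dp = bragg_elf_curve(beam, proton_stack, include_straggling=False)
        # brute-force Euler stepping at 1 um from the sample entrance energy
        e = dp.metadata["energy_at_sample_MeV"]
        step = 1e-4  # cm
        rho = SUPER_FRICKE.density
        deposit = np.zeros(dp.depth_grid.size)
        steps_per_bin = int(round(dp.grid_step / (step * 10.0)))
        k = 0
        while e > 0.55:
            de = mass_stopping_power(e, SUPER_FRICKE, PROTON) * rho * step
            de = min(de, e)
            deposit[min(k // steps_per_bin, deposit.size - 1)] += de
            e -= de
            k += 1
        deposit[min(k // steps_per_bin, deposit.size - 1)] += e  # sub-cutoff
        oracle = deposit / dp.grid_step
        peak = np.argmax(oracle)
        away = np.abs(np.arange(oracle.size) - peak) > 2
        mask = away & (oracle > 0.01 * oracle.max())
        rel = np.abs(dp.elf[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 0.02

    def test_beam_stopped_before_sample_warns_zero(self):
        stack = MaterialStack(((PMMA, 60.0), (SUPER_FRICKE, 10.0)), 1)
        with pytest.warns(UserWarning, match="does not reach"):
            dp = bragg_elf_curve(proton_beam(), stack)
        assert np.all(dp.elf == 0)

    def test_grid_step_must_resolve_fibre_pitch(self, proton_stack):
        with pytest.raises(ValueError, match="grid_step"):
            bragg_elf_curve(proton_beam(), proton_stack, grid_step=0.2)

    def test_carbon_peak_narrower_than_proton(
        self, proton_profile, carbon_profile
    ):
        def fwhm(dp):
            half = dp.elf.max() / 2
            idx = np.flatnonzero(dp.elf >= half)
            return (idx[-1] - idx[0]) * dp.grid_step

        assert fwhm(carbon_profile) < 0.5 * fwhm(proton_profile)


class TestDoseRateProfile:
    def test_linear_in_current(self, proton_profile, proton_stack):
        b1 = proton_beam(1.0)
        b2 = proton_beam(2.0)
        d1 = dose_rate_profile(proton_profile, b1)
        d2 = dose_rate_profile(proton_profile, b2)
        np.testing.assert_array_equal(d2, 2.0 * d1)

    def test_single_charge_differs_by_charge_state(self, carbon_profile):
        beam = carbon_beam()
        d = dose_rate_profile(carbon_profile, beam)
        d_strict = dose_rate_profile(carbon_profile, beam, single_charge=True)
        np.testing.assert_allclose(d_strict, 6.0 * d, rtol=1e-12)


def test_depth_profile_tsv_round_trip(tmp_path, proton_profile):
    path = tmp_path / "elf.tsv"
    proton_profile.to_tsv(path)
    assert path.read_text().startswith("# elf\n")
    back = DepthProfile.from_tsv(path)
    np.testing.assert_allclose(back.depth_grid, proton_profile.depth_grid,
                               atol=1e-6)
    np.testing.assert_allclose(back.elf, proton_profile.elf, rtol=1e-6)


def test_depth_profile_validates_grid():
    with pytest.raises(ValueError, match="increasing"):
        DepthProfile(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    with pytest.raises(ValueError, match="uniform"):
        DepthProfile(np.array([0.0, 1.0, 3.0]), np.zeros(3))
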