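import dataclasses

import numpy as np
import pytest

from hemafluor import (
    ConcentrationField,
    ExcitationSource,
    FluorophoreSpec,
    PatientProfile,
    generate_absorption_spectrum,
    generate_cbc,
    generate_eem,
    generate_patient_spectrum,
    generate_scattering_profile,
    mch_range_for_age,
)
from hemafluor.spectra import gaussian
from hemafluor.synthetic import (
    HB_ABSORPTION_SIGMA_NM,
    HB_DEOXY_BASE_AMPLITUDE,
    patient_band_components,
)


class TestGenerateEEM:
    def test_single_fluorophore_argmax_at_centers(self, broadband, ex_grid, em_grid):
        f = FluorophoreSpec(
            name="NADH", ex_center=350.0, ex_width=10.0, em_center=455.0, em_width=5.0,
            quantum_yield=0.5, molar_absorptivity=6000.0, concentration=1e-5,
        )
        eem = generate_eem([f], broadband, ex_grid, em_grid)
        ex_peak, em_peak = eem.argmax_wavelengths()
        assert abs(ex_peak - 350.0) <= 2.0
        assert abs(em_peak - 455.0) <= 2.0

    def test_zero_quantum_yield_gives_zero_eem(self, library, broadband, ex_grid, em_grid):
        dark = [dataclasses.replace(f, quantum_yield=0.0) for f in library]
        eem = generate_eem(dark, broadband, ex_grid, em_grid)
        assert np.all(eem.intensities == 0.0)

    def test_nadh_dominates_default_library(self, library, broadband, ex_grid, em_grid):
        eem = generate_eem(library, broadband, ex_grid, em_grid)
        ex_peak, em_peak = eem.argmax_wavelengths()
        nadh = next(f for f in library if f.name == "NADH")
        assert abs(ex_peak - nadh.ex_center) <= 6.0
        assert abs(em_peak - nadh.em_center) <= 6.0

    def test_seed_determinism(self, library, broadband, ex_grid, em_grid):
        a = generate_eem(library, broadband, ex_grid, em_grid, noise_sd=0.05, seed=42)
        b = generate_eem(library, broadband, ex_grid, em_grid, noise_sd=0.05, seed=42)
        assert np.array_equal(a.intensities, b.intensities)

    def test_spatial_field_scales_intensity(self, library, broadband, ex_grid, em_grid):
        x = y = z = np.linspace(0.0, 1.0, 5)
        field = ConcentrationField(x, y, z, np.full((5, 5, 5), 2.0))
        assert field.total() == pytest.approx(2.0)
        flat = generate_eem(library, broadband, ex_grid, em_grid)
        scaled = generate_eem(library, broadband, ex_grid, em_grid, field_=field)
        assert np.allclose(scaled.intensities, 2.0 * flat.intensities)

    def test_errors(self, library, broadband, ex_grid, em_grid):
        with pytest.raises(ValueError):
            generate_eem([], broadband, ex_grid, em_grid)
        with pytest.raises(ValueError):
            generate_eem(library, broadband, ex_grid[::-1], em_grid)
        with pytest.raises(ValueError):
            generate_eem(library, broadband, ex_grid, em_grid, noise_sd=-0.1)

    def test_stokes_violation_rejected(self):
        with pytest.raises(ValueError):
            FluorophoreSpec(
                name="bad", ex_center=500.0, ex_width=10.0, em_center=400.0, em_width=5.0,
                quantum_yield=0.5, molar_absorptivity=1.0, concentration=1.0,
            )


class TestAbsorptionSpectrum:
    @pytest.fixture
    def grid(self):
        return np.arange(400.0, 700.0 + 1e-9, 0.5)

    def test_peak_near_550(self, grid):
        s = generate_absorption_spectrum(0.9, 5.0, grid)
        assert s.wavelengths[np.argmax(s.intensities)] == pytest.approx(550.0)
        assert s.role == "absorbance"

    def test_height_increases_with_oxygen(self, grid):
        low = generate_absorption_spectrum(0.1, 5.0, grid)
        high = generate_absorption_spectrum(0.9, 5.0, grid)
        assert high.intensities.max() > low.intensities.max()

    def test_height_decreases_with_glycation(self, grid):
        g5 = generate_absorption_spectrum(0.5, 5.0, grid)
        g10 = generate_absorption_spectrum(0.5, 10.0, grid)
        assert g10.intensities.max() < g5.intensities.max()

    def test_deoxy_baseline_exact(self, grid):
        s = generate_absorption_spectrum(0.0, 0.0, grid, background=0.0)
        expected = HB_DEOXY_BASE_AMPLITUDE * gaussian(grid, 550.0, HB_ABSORPTION_SIGMA_NM)
        assert np.array_equal(s.intensities, expected)

    def test_deterministic(self, grid):
        a = generate_absorption_spectrum(0.7, 6.0, grid)
        b = generate_absorption_spectrum(0.7, 6.0, grid)
        assert np.array_equal(a.intensities, b.intensities)

    def test_errors(self, grid):
        with pytest.raises(ValueError):
            generate_absorption_spectrum(1.5, 5.0, grid)
        with pytest.raises(ValueError):
            generate_absorption_spectrum(0.5, -1.0, grid)
        with pytest.raises(ValueError):
            generate_absorption_spectrum(0.5, 5.0, np.arange(500.0, 600.0, 0.5))


class TestPatientSpectrum:
    def test_lower_oxygen_larger_deoxy_integral(self, broadband, full_grid):
        from hemafluor import integrate_intensity

        base = dict(hemoglobin_gdl=14.0, plasma_fraction=0.5, noise_sd=0.0)
        hi = generate_patient_spectrum(
            PatientProfile(oxygen_fraction=0.95, **base), broadband, full_grid
        )
        lo = generate_patient_spectrum(
            PatientProfile(oxygen_fraction=0.60, **base), broadband, full_grid
        )
        assert integrate_intensity(lo, 600.0, 700.0) > integrate_intensity(hi, 600.0, 700.0)

    def test_zero_plasma_component_identically_zero(self, broadband, full_grid):
        profile = PatientProfile(hemoglobin_gdl=14.0, oxygen_fraction=0.9, plasma_fraction=0.0)
        components = patient_band_components(profile, broadband, full_grid)
        assert np.all(components["plasma"] == 0.0)

    def test_young_exceeds_old(self, broadband, full_grid):
        from hemafluor import integrate_intensity

        base = dict(hemoglobin_gdl=14.0, oxygen_fraction=0.8, plasma_fraction=0.5)
        young = generate_patient_spectrum(
            PatientProfile(lifecycle_phase="young", **base), broadband, full_grid
        )
        old = generate_patient_spectrum(
            PatientProfile(lifecycle_phase="old", **base), broadband, full_grid
        )
        assert integrate_intensity(young, 200.0, 900.0) > integrate_intensity(old, 200.0, 900.0)

    def test_hb_monotonicity_of_hb_oxy_band(self, broadband, full_grid):
        """400-600 nm integral strictly increases in hemoglobin over 10 values."""
        from hemafluor import integrate_intensity

        integrals = []
        for hb in np.linspace(8.0, 18.0, 10):
            s = generate_patient_spectrum(
                PatientProfile(hemoglobin_gdl=float(hb), oxygen_fraction=0.9,
                               plasma_fraction=0.5),
                broadband, full_grid,
            )
            integrals.append(integrate_intensity(s, 400.0, 600.0))
        assert np.all(np.diff(integrals) > 0)

    def test_noise_clipped_except_uv(self, full_grid):
        profile = PatientProfile(
            hemoglobin_gdl=1e-6 + 0.5, oxygen_fraction=0.5, plasma_fraction=0.0,
            noise_sd=0.5, seed=3,
        )
        clipped = generate_patient_spectrum(profile, ExcitationSource("halogen"), full_grid)
        assert np.all(clipped.intensities >= 0.0)
        uv = generate_patient_spectrum(profile, ExcitationSource("UV"), full_grid)
        assert np.any(uv.intensities < 0.0)

    def test_seed_determinism(self, broadband, full_grid):
        profile = PatientProfile(
            hemoglobin_gdl=14.0, oxygen_fraction=0.9, plasma_fraction=0.5,
            noise_sd=0.1, seed=7,
        )
        a = generate_patient_spectrum(profile, broadband, full_grid)
        b = generate_patient_spectrum(profile, broadband, full_grid)
        assert np.array_equal(a.intensities, b.intensities)

    def test_invalid_profile(self):
        with pytest.raises(ValueError):
            PatientProfile(hemoglobin_gdl=-1.0, oxygen_fraction=0.5)
        with pytest.raises(ValueError):
            PatientProfile(hemoglobin_gdl=14.0, oxygen_fraction=1.5)


class TestGenerateCBC:
    def test_adult_mch_in_range(self):
        for seed in range(5):
            rec = generate_cbc(20.0, "F", seed=seed)
            assert 27.0 <= rec.mch_pg <= 34.0

    def test_child_mch_in_range(self):
        rec = generate_cbc(7.0, "M", seed=1)
        assert 24.0 <= rec.mch_pg <= 30.0

    def test_iron_deficiency_below_range(self):
        for seed in range(5):
            rec = generate_cbc(20.0, "F", condition="iron_deficiency", seed=seed)
            assert rec.mch_pg < 27.0

    def test_b12_deficiency_above_range(self):
        rec = generate_cbc(20.0, "M", condition="b12_deficiency", seed=2)
        assert rec.mch_pg > 34.0

    def test_self_consistency(self):
        for seed in range(10):
            rec = generate_cbc(33.0, "F", seed=seed)
            implied_hb = rec.rbc_1e6_per_ul * rec.mch_pg / 10.0
            assert abs(rec.hb_gdl - implied_hb) / rec.hb_gdl < 1e-6

    def test_determinism(self):
        a = generate_cbc(40.0, "M", seed=9)
        b = generate_cbc(40.0, "M", seed=9)
        assert a == b

    def test_age_below_bin_rejected(self):
        with pytest.raises(ValueError):
            generate_cbc(0.2, "F")

    def test_older_adults_reuse_adult_bin(self):
        assert mch_range_for_age(70.0) == (27.0, 34.0)


class TestScatteringProfile:
    def test_peak_position_from_diameter(self):
        grid = np.arange(400.0, 900.0 + 1e-9, 0.5)
        s = generate_scattering_profile(7.2, 0.009, grid)
        assert s.wavelengths[np.argmax(s.intensities)] == pytest.approx(800.0)

    def test_determinism(self):
        grid = np.arange(400.0, 900.0 + 1e-9, 0.5)
        a = generate_scattering_profile(7.2, 0.009, grid, noise_sd=0.0, seed=1)
        b = generate_scattering_profile(7.2, 0.009, grid, noise_sd=0.0, seed=1)
        assert np.array_equal(a.intensities, b.intensities)

    def test_peak_outside_grid_rejected(self):
        grid = np.arange(400.0, 700.0 + 1e-9, 0.5)
        with pytest.raises(ValueError):
            generate_scattering_profile(9.0, 0.009, grid)  # implies 1000 nm
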