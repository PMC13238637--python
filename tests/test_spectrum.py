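"""Spectral model: generation, filtration, contrast, kerma and HVL."""

import numpy as np
import pytest

from lcphantom.materials import get_material
from lcphantom.spectrum import (
    DEFAULT_BEAMS,
    BeamQuality,
    EnergyGrid,
    Spectrum,
    air_kerma,
    attenuate,
    generate_spectrum,
    hvl_al,
    load_beams,
    mean_energy,
    subject_contrast,
    subject_contrast_spectrum,
    total_fluence,
)


class TestGenerateSpectrum:
    def test_zero_fluence_above_tube_potential(self):
        grid = EnergyGrid.for_kvp(80.0)
        s = generate_spectrum(BeamQuality("b", 65.0, added_cu_mm=0.3), grid)
        above = grid.centers > 65.0
        assert above.any()
        assert np.all(s.fluence[above] == 0)
        assert np.all(s.fluence >= 0)

    def test_higher_kvp_populates_harder_bins(self):
        grid = EnergyGrid.for_kvp(100.0)
        s65 = generate_spectrum(BeamQuality("b", 65.0, added_cu_mm=0.3), grid)
        s100 = generate_spectrum(BeamQuality("b", 100.0, added_cu_mm=0.3), grid)
        band = (grid.centers > 65.0) & (grid.centers < 100.0)
        assert np.all(s65.fluence[band] == 0)
        assert np.any(s100.fluence[band] > 0)

    def test_filtration_hardens_beam(self):
        unfiltered = generate_spectrum(
            BeamQuality("b", 100.0, added_cu_mm=0.0, inherent_al_mm=0.0)
        )
        filtered = generate_spectrum(BeamQuality("b", 100.0, added_cu_mm=0.9))
        assert mean_energy(filtered) > mean_energy(unfiltered)

    def test_kvp_out_of_model_range_rejected(self):
        with pytest.raises(ValueError, match="150"):
            BeamQuality("b", 200.0)
        with pytest.raises(ValueError, match="10"):
            BeamQuality("b", 5.0)

    def test_bundled_beam_config_matches_reference_settings(self):
        beams = load_beams()
        assert [beams[q].kvp for q in ("Q1", "Q2", "Q3")] == [65.0, 80.0, 100.0]
        assert [beams[q].added_cu_mm for q in ("Q1", "Q2", "Q3")] == [0.3, 0.6, 0.9]
        assert all(beams[q].fdd_mm == 1000.0 for q in beams)


class TestAttenuate:
    def test_zero_thickness_is_identity(self, q1):
        s = generate_spectrum(q1)
        out = attenuate(s, get_material("pmma"), 0.0)
        np.testing.assert_array_equal(out.fluence, s.fluence)

    def test_half_value_closed_form_single_bin(self):
        al = get_material("aluminium")
        s = Spectrum.monoenergetic(50.0, fluence=8.0)
        mu = float(al.linear_attenuation(np.array([50.0]))[0])  # 1/cm
        t_mm = 10.0 * np.log(2) / mu
        out = attenuate(s, al, t_mm)
        assert out.fluence[0] == pytest.approx(4.0, rel=1e-12)

    def test_order_of_filters_commutes(self, q1):
        s = generate_spectrum(q1)
        cu, al = get_material("copper"), get_material("aluminium")
        a = attenuate(attenuate(s, cu, 0.2), al, 1.5)
        b = attenuate(attenuate(s, al, 1.5), cu, 0.2)
        np.testing.assert_allclose(a.fluence, b.fluence, rtol=1e-12)

    def test_thickness_composes_additively(self, q1):
        s = generate_spectrum(q1)
        pmma = get_material("pmma")
        a = attenuate(attenuate(s, pmma, 3.3), pmma, 6.7)
        b = attenuate(s, pmma, 10.0)
        np.testing.assert_allclose(a.fluence, b.fluence, rtol=1e-12)

    def test_negative_thickness_rejected(self, q1):
        with pytest.raises(ValueError):
            attenuate(generate_spectrum(q1), get_material("pmma"), -1.0)


class TestTotalFluence:
    def test_single_bin(self):
        s = Spectrum.monoenergetic(40.0, fluence=3.0, bin_width=0.5)
        assert total_fluence(s) == pytest.approx(1.5)

    def test_zero_spectrum(self):
        grid = EnergyGrid.for_kvp(65.0)
        assert total_fluence(Spectrum(grid, np.zeros(grid.centers.size))) == 0.0

    def test_riemann_refinement_converges(self, q1):
        coarse = total_fluence(generate_spectrum(q1, EnergyGrid.for_kvp(65.0, 0.5)))
        fine = total_fluence(generate_spectrum(q1, EnergyGrid.for_kvp(65.0, 0.25)))
        assert abs(fine - coarse) / fine < 1e-3


class TestSubjectContrast:
    def test_zero_depth_gives_zero(self, q1, pmma):
        assert subject_contrast(q1, pmma, 10.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_monoenergetic_closed_form(self, pmma):
        s = Spectrum.monoenergetic(45.0)
        mu = float(pmma.linear_attenuation(np.array([45.0]))[0])
        for d_mm in (0.2, 1.0, 2.2):
            expected = 100.0 * (np.exp(mu * d_mm / 10.0) - 1.0)
            got = subject_contrast_spectrum(s, pmma, 10.0, d_mm)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_polyenergetic_bracketed_by_monoenergetic_extremes(self, q1, pmma):
        s = generate_spectrum(q1)
        populated = s.grid.centers[s.fluence > 1e-12 * s.fluence.max()]
        mu_lo = float(pmma.linear_attenuation(np.array([populated.max()]))[0])
        mu_hi = float(pmma.linear_attenuation(np.array([populated.min()]))[0])
        sc = subject_contrast(q1, pmma, 10.0, 1.0)
        assert 100.0 * (np.exp(mu_lo * 0.1) - 1.0) <= sc <= 100.0 * (np.exp(mu_hi * 0.1) - 1.0)

    def test_strictly_increasing_in_depth(self, q1, pmma):
        depths = np.arange(0.0, 2.6, 0.1)
        sc = [subject_contrast(q1, pmma, 10.0, d) for d in depths]
        assert np.all(np.diff(sc) > 0)

    def test_harder_beam_reduces_contrast(self, pmma):
        for depth in (0.5, 1.0, 2.0):
            sc = [
                subject_contrast(DEFAULT_BEAMS[q], pmma, 10.0, depth)
                for q in ("Q1", "Q2", "Q3")
            ]
            assert sc[0] > sc[1] > sc[2]

    def test_copper_filtration_reduces_contrast_at_fixed_kvp(self, pmma):
        for depth in (0.5, 1.5):
            sc_soft = subject_contrast(BeamQuality("b", 80.0, added_cu_mm=0.1), pmma, 10.0, depth)
            sc_hard = subject_contrast(BeamQuality("b", 80.0, added_cu_mm=0.9), pmma, 10.0, depth)
            assert sc_hard < sc_soft

    def test_hole_deeper_than_plate_rejected(self, q1, pmma):
        with pytest.raises(ValueError):
            subject_contrast(q1, pmma, 10.0, 11.0)


class TestAirKerma:
    def test_zero_spectrum(self):
        grid = EnergyGrid.for_kvp(65.0)
        assert air_kerma(Spectrum(grid, np.zeros(grid.centers.size))) == 0.0

    def test_linearity_in_fluence(self, q1):
        s = generate_spectrum(q1)
        doubled = Spectrum(s.grid, 2 * s.fluence)
        assert air_kerma(doubled) == pytest.approx(2 * air_kerma(s), rel=1e-12)

    def test_monoenergetic_hand_arithmetic(self):
        air = get_material("air")
        s = Spectrum.monoenergetic(50.0, fluence=2.0, bin_width=0.5)
        muen = float(air.mass_energy_absorption(np.array([50.0]))[0])
        assert air_kerma(s) == pytest.approx(2.0 * 50.0 * muen * 0.5, rel=1e-12)

    def test_missing_muen_table_rejected(self, q1):
        s = generate_spectrum(q1)
        with pytest.raises(ValueError):
            air_kerma(s, air=get_material("pmma"))


class TestHvl:
    def test_monoenergetic_closed_form(self):
        al = get_material("aluminium")
        for e in (30.0, 60.0, 100.0):
            s = Spectrum.monoenergetic(e)
            expected_mm = 10.0 * np.log(2) / float(al.linear_attenuation(np.array([e]))[0])
            assert hvl_al(s) == pytest.approx(expected_mm, abs=2e-3)

    def test_halving_property_on_reattenuation(self, q1):
        s = generate_spectrum(q1)
        t = hvl_al(s, tol_mm=1e-6)
        ratio = air_kerma(attenuate(s, get_material("aluminium"), t)) / air_kerma(s)
        assert ratio == pytest.approx(0.5, rel=1e-3)

    def test_prefiltration_increases_hvl(self, q1):
        s = generate_spectrum(q1)
        hardened = attenuate(s, get_material("copper"), 0.1)
        assert hvl_al(hardened) > hvl_al(s)

    def test_zero_spectrum_rejected(self):
        grid = EnergyGrid.for_kvp(65.0)
        with pytest.raises(ValueError):
            hvl_al(Spectrum(grid, np.zeros(grid.centers.size)))

    def test_fluence_weighted_hvl_differs_from_kerma_hvl(self, q1):
        s = generate_spectrum(q1)
        assert hvl_al(s, on="fluence") != pytest.approx(hvl_al(s, on="kerma"), abs=1e-4)
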