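import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import photodose as pv
from photodose.spectra import Spectrum, LaserLine

from conftest import gaussian_spectrum


class TestResample:
    def test_identity_on_own_grid(self, fixture_set):
        s = fixture_set.led_spectrum
        r = s.resample(s.wavelengths_nm)
        np.testing.assert_array_equal(r.values, s.values)

    def test_linear_midpoint(self):
        s = Spectrum([690.0, 700.0], [0.0, 10.0])
        assert s(np.array([695.0]))[0] == pytest.approx(5.0)

    def test_zero_outside_support(self):
        s = Spectrum([690.0, 700.0], [1.0, 10.0])
        assert s(np.array([650.0]))[0] == 0.0
        assert s(np.array([710.0]))[0] == 0.0

    def test_empty_grid_rejected(self):
        s = Spectrum([690.0, 700.0], [0.0, 10.0])
        with pytest.raises(ValueError, match="empty"):
            s.resample(np.array([]))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Spectrum([700.0, 690.0], [1.0, 1.0])      # not increasing
        with pytest.raises(ValueError):
            Spectrum([690.0, 700.0], [-1.0, 1.0])     # negative value
        with pytest.raises(ValueError):
            Spectrum([690.0, 700.0], [0.0, 0.0])      # identically zero

    def test_csv_round_trip(self, tmp_path, fixture_set):
        path = tmp_path / "led.csv"
        fixture_set.led_spectrum.to_csv(path, comment="round trip")
        back = Spectrum.from_csv(path)
        np.testing.assert_allclose(back.values, fixture_set.led_spectrum.values,
                                   rtol=1e-9)


class TestFwhm:
    def test_led_fixture_crossings(self, fixture_set):
        lo, hi = pv.fwhm_interval(fixture_set.led_spectrum)
        assert lo == pytest.approx(676.0, abs=0.05)
        assert hi == pytest.approx(702.0, abs=0.05)

    @pytest.mark.parametrize("sigma", [3.0, 8.0, 15.0])
    def test_gaussian_closed_form(self, sigma):
        grid = np.arange(550.0, 850.0, 0.1)
        s = Spectrum(grid, np.exp(-0.5 * ((grid - 690.0) / sigma) ** 2))
        lo, hi = pv.fwhm_interval(s)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
        assert hi - lo == pytest.approx(expected, abs=0.01)

    def test_triangle_half_width(self):
        # triangular peak from 685 to 695: half-height crossings 5 nm apart
        grid = np.array([680.0, 685.0, 690.0, 695.0, 700.0])
        s = Spectrum(grid, np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
        lo, hi = pv.fwhm_interval(s)
        assert hi - lo == pytest.approx(5.0)
        assert (lo, hi) == (pytest.approx(687.5), pytest.approx(692.5))

    def test_flat_spectrum_rejected(self):
        s = Spectrum(np.arange(600.0, 700.0), np.ones(100))
        with pytest.raises(ValueError, match="flat"):
            pv.fwhm_interval(s)

    def test_multimodal_rejected_but_ripple_ignored(self):
        grid = np.arange(600.0, 780.0, 0.25)
        two = (np.exp(-0.5 * ((grid - 650.0) / 5.0) ** 2)
               + 0.8 * np.exp(-0.5 * ((grid - 730.0) / 5.0) ** 2))
        with pytest.raises(ValueError, match="multimodal"):
            pv.fwhm_interval(Spectrum(grid, two))
        rng = np.random.default_rng(0)
        rippled = np.exp(-0.5 * ((grid - 690.0) / 8.0) ** 2)
        rippled *= 1.0 + 0.003 * rng.standard_normal(grid.size)
        lo, hi = pv.fwhm_interval(Spectrum(grid, np.clip(rippled, 0, None)))
        assert lo < 690.0 < hi


def _riemann_epsilon(source, absorber, ref_nm, dx=0.002):
    """Independent midpoint-Riemann oracle for the overlap efficiency."""
    lo, hi = source.support
    mid = np.arange(lo, hi, dx) + dx / 2.0
    s = source(mid)
    a = absorber(mid)
    return (np.sum(s * a) / np.sum(s)) / absorber(np.array([ref_nm]))[0]


class TestSpectralEfficiency:
    def test_constant_absorber_gives_unity(self, fixture_set):
        grid = np.arange(600.0, 780.0, 0.5)
        flat = Spectrum(grid, np.full(grid.size, 3.7))
        eff = pv.spectral_efficiency(fixture_set.led_spectrum, flat,
                                     LaserLine(690.0))
        assert eff.epsilon == pytest.approx(1.0, abs=1e-12)
        assert eff.detector_correction == 1.0

    def test_delta_source_limit(self, fixture_set):
        eps = []
        for fwhm in (8.0, 2.0, 0.25):
            grid = np.arange(680.0, 700.0, 0.02)
            src = gaussian_spectrum(690.0, fwhm, grid)
            eps.append(pv.spectral_efficiency(
                src, fixture_set.absorber_spectrum, LaserLine(690.0)).epsilon)
        assert eps == sorted(eps)          # approaches 1 from below
        assert eps[-1] == pytest.approx(1.0, abs=1e-3)

    def test_narrowing_gaussian_monotone(self, fixture_set):
        widths = [2.0, 6.0, 12.0, 20.0, 30.0]
        eps = [pv.spectral_efficiency(gaussian_spectrum(690.0, w),
                                      fixture_set.absorber_spectrum,
                                      LaserLine(690.0)).epsilon
               for w in widths]
        assert all(a >= b for a, b in zip(eps, eps[1:]))

    def test_agrees_with_riemann_oracle(self, fixture_set):
        eff = pv.spectral_efficiency(fixture_set.led_spectrum,
                                     fixture_set.absorber_spectrum,
                                     LaserLine(690.0))
        oracle = _riemann_epsilon(fixture_set.led_spectrum,
                                  fixture_set.absorber_spectrum, 690.0)
        assert eff.epsilon == pytest.approx(oracle, rel=1e-6)

    def test_peak_shift_sensitivity_below_one_percent(self, fixture_set):
        e0 = pv.spectral_efficiency(fixture_set.led_spectrum,
                                    fixture_set.absorber_spectrum,
                                    LaserLine(690.0)).epsilon
        e1 = pv.spectral_efficiency(fixture_set.led_spectrum.shifted(0.2),
                                    fixture_set.absorber_spectrum,
                                    LaserLine(690.0)).epsilon
        assert abs(e1 - e0) / e0 < 0.01

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale_s=st.floats(0.01, 100.0), scale_a=st.floats(0.01, 100.0),
           scale_d=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale_s, scale_a, scale_d):
        fx = pv.generate_fixtures(seed=1)
        base = pv.spectral_efficiency(fx.led_spectrum, fx.absorber_spectrum,
                                      LaserLine(690.0), fx.detector_spectrum)
        scaled = pv.spectral_efficiency(fx.led_spectrum.scaled(scale_s),
                                        fx.absorber_spectrum.scaled(scale_a),
                                        LaserLine(690.0),
                                        fx.detector_spectrum.scaled(scale_d))
        assert scaled.epsilon == pytest.approx(base.epsilon, rel=1e-9)
        assert scaled.detector_correction == pytest.approx(
            base.detector_correction, rel=1e-9)

    def test_flat_detector_correction_near_unity(self, fixture_set):
        eff = pv.spectral_efficiency(fixture_set.led_spectrum,
                                     fixture_set.absorber_spectrum,
                                     LaserLine(690.0),
                                     fixture_set.detector_spectrum)
        assert eff.detector_correction == pytest.approx(1.0, abs=0.01)

    def test_photon_weighting_close_but_distinct(self, fixture_set):
        e_en = pv.spectral_efficiency(fixture_set.led_spectrum,
                                      fixture_set.absorber_spectrum,
                                      LaserLine(690.0)).epsilon
        e_ph = pv.spectral_efficiency(fixture_set.led_spectrum,
                                      fixture_set.absorber_spectrum,
                                      LaserLine(690.0),
                                      weighting="photon").epsilon
        assert e_ph == pytest.approx(e_en, rel=0.02)
        assert e_ph != e_en

    def test_zero_absorber_at_reference_rejected(self, fixture_set):
        grid = np.arange(600.0, 650.0, 0.5)
        off_band = Spectrum(grid, np.exp(-0.5 * ((grid - 620.0) / 5.0) ** 2))
        with pytest.raises(ValueError, match="reference"):
            pv.spectral_efficiency(fixture_set.led_spectrum, off_band,
                                   LaserLine(690.0))

    def test_disjoint_supports_rejected(self):
        src = gaussian_spectrum(690.0, 10.0, np.arange(680.0, 700.0, 0.1))
        absorber = Spectrum(np.arange(500.0, 540.0, 0.5),
                            np.ones(80))
        with pytest.raises(ValueError):
            pv.spectral_efficiency(src, absorber, LaserLine(690.0))


class TestEffectiveDose:
    def test_arithmetic_and_identity(self):
        eff = pv.SpectralEfficiency(epsilon=0.6198, detector_correction=1.05,
                                    reference_nm=690.0)
        assert pv.effective_dose(10.0, eff) == pytest.approx(6.198)
        assert pv.effective_dose(0.0, eff) == 0.0
        unit = pv.SpectralEfficiency(1.0, 1.0, 690.0)
        assert pv.effective_dose(7.5, unit) == 7.5

    def test_reading_correction_divides(self):
        eff = pv.SpectralEfficiency(epsilon=0.6, detector_correction=1.25,
                                    reference_nm=690.0)
        assert pv.correct_reading(125.0, eff) == pytest.approx(100.0)

    def test_negative_dose_rejected(self):
        eff = pv.SpectralEfficiency(1.0, 1.0, 690.0)
        with pytest.raises(ValueError):
            pv.effective_dose(-1.0, eff)
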