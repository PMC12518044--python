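import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dporkin.errors import CalibrationError, InvalidInputError
from dporkin.references import (ReferenceSet, ReferenceSpectrum,
                                SmoothingConfig, calibrate_es_epsilon,
                                read_reference_set, smooth_reference,
                                to_epsilon, write_reference_set)
from dporkin.spectra import Spectrum
from dporkin.synth import (NoiseModel, default_bands, generate_experiment,
                           get_scenario, make_reference_set)

GRID = np.arange(600.0, 701.0, 1.0)


def gaussian_band(peak_au=0.25, center=651.0, sigma=12.0):
    return peak_au * np.exp(-0.5 * ((GRID - center) / sigma) ** 2)


class TestSmoothReference:
    def test_zero_smoothing_is_identity(self, rng):
        s = Spectrum(GRID, gaussian_band() + rng.normal(0, 0.01, GRID.size))
        out = smooth_reference(s, SmoothingConfig(lam=0))
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_gcv_smoothing_recovers_noise_free_band(self, rng):
        truth = gaussian_band()
        noisy = Spectrum(GRID, truth + rng.normal(0, 0.002, GRID.size))
        out = smooth_reference(noisy)
        assert np.max(np.abs(out.absorbance - truth)) < 0.004

    def test_residuals_have_no_systematic_trend(self, rng):
        truth = gaussian_band()
        noisy = Spectrum(GRID, truth + rng.normal(0, 0.002, GRID.size))
        out = smooth_reference(noisy)
        resid = noisy.absorbance - out.absorbance
        assert abs(np.mean(resid)) < 3 * 0.002 / np.sqrt(GRID.size)

    def test_too_few_points_rejected(self):
        s = Spectrum(GRID[:5], np.zeros(5))
        with pytest.raises(InvalidInputError):
            smooth_reference(s)

    def test_negative_parameter_rejected(self):
        with pytest.raises(InvalidInputError):
            SmoothingConfig(lam=-1.0)


class TestToEpsilon:
    @pytest.mark.parametrize("a_peak, conc, expected", [
        (0.1872, 8.0, 23.4),   # substrate Q-band at 651 nm
        (0.2235, 5.0, 44.7),   # product band at 670 nm
    ])
    def test_beer_lambert_arithmetic(self, a_peak, conc, expected):
        s = Spectrum(GRID, np.full(GRID.size, a_peak))
        eps = to_epsilon(s, conc, 1.0)
        np.testing.assert_allclose(eps, expected, rtol=1e-12)

    def test_zero_absorbance_gives_zero_epsilon(self):
        s = Spectrum(GRID, np.zeros(GRID.size))
        assert np.all(to_epsilon(s, 8.0) == 0.0)

    def test_nonpositive_concentration_rejected(self):
        s = Spectrum(GRID, np.ones(GRID.size))
        with pytest.raises(InvalidInputError):
            to_epsilon(s, 0.0)

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_beer_lambert_scale_invariance(self, k):
        # epsilon(k*A, k*c) == epsilon(A, c)
        a = gaussian_band()
        base = to_epsilon(Spectrum(GRID, a), 8.0)
        scaled = to_epsilon(Spectrum(GRID, k * a), k * 8.0)
        np.testing.assert_allclose(scaled, base, rtol=1e-9)

    def test_round_trip_reproduces_absorbance(self):
        a = gaussian_band()
        eps = to_epsilon(Spectrum(GRID, a), 8.0, 1.0)
        np.testing.assert_allclose(eps * 8.0e-3 * 1.0, a, rtol=0, atol=1e-15)


class TestReferenceSpectrum:
    def test_peak_location_and_value(self):
        refs, raw = make_reference_set()
        ref = ReferenceSpectrum.from_raw("S", raw["S"], 8.0,
                                         SmoothingConfig(lam=0))
        wl, eps = ref.peak()
        assert wl == 651.0
        np.testing.assert_allclose(eps, 23.4, rtol=1e-12)

    def test_unknown_species_rejected(self):
        s = Spectrum(GRID, gaussian_band())
        with pytest.raises(InvalidInputError):
            ReferenceSpectrum("X", s, 8.0, np.zeros(GRID.size))


class TestReferenceSetIO:
    def test_csv_round_trip(self, refs, tmp_path):
        path = tmp_path / "refs.csv"
        write_reference_set(refs, path)
        back = read_reference_set(path)
        np.testing.assert_allclose(back.eps_ES, refs.eps_ES, rtol=1e-9)
        assert back.ref_concentrations_uM == refs.ref_concentrations_uM
        assert back.analysis_window == refs.analysis_window

    def test_missing_species_rejected(self, raw_references):
        ref_s = ReferenceSpectrum.from_raw("S", raw_references["S"], 8.0,
                                           SmoothingConfig(lam=0))
        with pytest.raises(InvalidInputError):
            ReferenceSet.from_references({"S": ref_s})


def _binding_series(noise, es_scale=1.0, every=6):
    """Spectra of a no-donor (S + ES only) experiment; optionally generated
    with an ES extinction coefficient scaled away from the nominal one."""
    bands = default_bands()
    if es_scale != 1.0:
        es = bands["ES"]
        bands = dict(bands)
        bands["ES"] = type(es)(es.center_nm, es.sigma_nm,
                               es.peak_epsilon * es_scale)
    scenario = get_scenario("preincubation", noise=noise)
    scenario = type(scenario)(**{**scenario.__dict__, "bands": bands})
    exp = generate_experiment(scenario, seed=7)
    return exp.stage_spectra(0)[::every], exp.refs


class TestEsCalibration:
    def test_consistent_references_give_unit_scale(self, clean_noise, refs):
        series, _ = _binding_series(clean_noise)
        alpha = calibrate_es_epsilon(series, refs, total_pchlide_uM=20.0)
        assert abs(alpha - 1.0) < 0.02

    def test_injected_miscalibration_recovered(self, clean_noise, refs):
        series, _ = _binding_series(clean_noise, es_scale=1.25)
        alpha = calibrate_es_epsilon(series, refs, total_pchlide_uM=20.0)
        assert abs(alpha - 1.25) < 0.03

    def test_calibration_idempotent(self, clean_noise, refs):
        series, _ = _binding_series(clean_noise, es_scale=1.25)
        alpha1 = calibrate_es_epsilon(series, refs, total_pchlide_uM=20.0)
        alpha2 = calibrate_es_epsilon(series, refs.scaled_es(alpha1),
                                      total_pchlide_uM=20.0)
        assert abs(alpha2 - 1.0) < 0.02

    def test_short_series_rejected(self, clean_noise, refs):
        series, _ = _binding_series(clean_noise)
        with pytest.raises(InvalidInputError):
            calibrate_es_epsilon(series[:3], refs, total_pchlide_uM=20.0)

    def test_wrong_total_raises_calibration_error(self, clean_noise, refs):
        series, _ = _binding_series(clean_noise)
        with pytest.raises(CalibrationError):
            calibrate_es_epsilon(series, refs, total_pchlide_uM=40.0)
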