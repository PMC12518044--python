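import numpy as np
import pytest

from dporkin.errors import InvalidInputError
from dporkin.spectra import Spectrum
from dporkin.synth import generate_experiment, get_scenario
from dporkin.unmix import (ConcentrationSeries, UnmixConfig,
                           conservation_check, model_spectrum, unmix_series,
                           unmix_spectrum)
from dporkin.unmix import _reference_bases, _window_mask


def mixture(refs, c_S=0.0, c_ES=0.0, c_P=0.0, p4=0.0, p5=0.0, exponent=3,
            noise_sd=0.0, rng=None):
    """Forward-model a mixture spectrum in uM on the reference grid."""
    grid = refs.common_grid
    a = ((refs.eps_S * c_S + refs.eps_ES * c_ES + refs.eps_P * c_P) * 1e-3
         * refs.path_length_cm + p4 + p5 * grid ** exponent)
    if noise_sd:
        a = a + rng.normal(0.0, noise_sd, grid.size)
    return Spectrum(grid, a)


class TestModelSpectrum:
    def test_pure_s_reference_identity(self, refs):
        out = model_spectrum([1.0], refs)
        m = _window_mask(refs, UnmixConfig())
        expected = _reference_bases(refs)["S"][m]
        np.testing.assert_allclose(out.absorbance, expected, rtol=1e-14)

    def test_flat_baseline_only(self, refs):
        out = model_spectrum([0.0, 0.0, 0.0, 0.05], refs)
        np.testing.assert_allclose(out.absorbance, 0.05)

    def test_linearity_average_of_two_species(self, refs):
        s = model_spectrum([1.0], refs).absorbance
        es = model_spectrum([0.0, 0.0, 1.0], refs).absorbance
        both = model_spectrum([0.5, 0.0, 0.5], refs).absorbance
        np.testing.assert_allclose(both, 0.5 * (s + es), rtol=1e-14)


class TestUnmixSpectrum:
    def test_noise_free_mixture_recovered_exactly(self, refs):
        spec = mixture(refs, c_S=10.0, c_ES=1.5, c_P=0.0)
        r = unmix_spectrum(spec, refs)
        assert abs(r.c_S_uM - 10.0) < 1e-6
        assert abs(r.c_ES_uM - 1.5) < 1e-6
        assert abs(r.c_P_uM) < 1e-6
        assert r.converged

    def test_pure_product_reference_recovery(self, refs):
        spec = mixture(refs, c_P=5.0)
        r = unmix_spectrum(spec, refs)
        np.testing.assert_allclose(r.c_P_uM, 5.0, atol=1e-8)
        assert abs(r.c_S_uM) < 1e-8 and abs(r.c_ES_uM) < 1e-8

    def test_all_zero_spectrum(self, refs):
        r = unmix_spectrum(mixture(refs), refs)
        for v in (r.c_S_uM, r.c_ES_uM, r.c_P_uM, r.p4):
            assert abs(v) < 1e-8

    def test_replicate_noise_mean_within_two_percent(self, refs, rng):
        truth = dict(c_S=10.0, c_ES=1.5, c_P=2.0)
        est = np.array([
            [r.c_S_uM, r.c_ES_uM, r.c_P_uM]
            for r in (unmix_spectrum(
                mixture(refs, **truth, noise_sd=0.002, rng=rng), refs)
                for _ in range(100))])
        np.testing.assert_allclose(est.mean(axis=0), [10.0, 1.5, 2.0],
                                   rtol=0.02)

    def test_linear_oracle_equivalence(self, refs, rng):
        # with shifts fixed the model is linear: the nonlinear solver must
        # agree with a direct linear least-squares solution
        cfg = UnmixConfig(nonneg_concentrations=False)
        m = _window_mask(refs, cfg)
        grid = refs.common_grid[m]
        b = _reference_bases(refs)
        B = np.column_stack([b["S"][m], b["P"][m], b["ES"][m],
                             np.ones(grid.size), (grid / 650.0) ** 3])
        for _ in range(20):
            p = np.concatenate([rng.uniform(0, 2, 3),
                                rng.uniform(-0.01, 0.01, 1),
                                rng.uniform(-0.02, 0.02, 1)])
            spec = Spectrum(grid, B @ p)
            r = unmix_spectrum(spec, refs, cfg)
            lin, *_ = np.linalg.lstsq(B, spec.absorbance, rcond=None)
            got = np.array([r.c_S_uM / 8, r.c_P_uM / 5, r.c_ES_uM / 3.5,
                            r.p4, r.p5 * 650.0 ** 3])
            np.testing.assert_allclose(got, lin, rtol=1e-8, atol=1e-12)

    def test_scale_equivariance(self, refs):
        spec = mixture(refs, c_S=4.0, c_ES=1.0, c_P=0.5, p4=0.01, p5=1e-11)
        r1 = unmix_spectrum(spec, refs)
        r3 = unmix_spectrum(Spectrum(spec.wavelength_nm, 3 * spec.absorbance),
                            refs)
        for a, b in [(r1.c_S_uM, r3.c_S_uM), (r1.c_ES_uM, r3.c_ES_uM),
                     (r1.c_P_uM, r3.c_P_uM), (r1.p4, r3.p4), (r1.p5, r3.p5)]:
            np.testing.assert_allclose(3 * a, b, rtol=1e-6, atol=1e-12)

    def test_free_shifts_recover_injected_shift(self, refs):
        # spectrum built with the S band displaced by +1 nm; the free-shift
        # fit should attribute it to p6, not distort the concentrations
        grid = refs.common_grid
        shifted_S = np.interp(grid - 1.0, grid, refs.eps_S)
        a = (shifted_S * 10.0 + refs.eps_ES * 1.5) * 1e-3
        r = unmix_spectrum(Spectrum(grid, a), refs,
                           UnmixConfig(fix_shifts=False))
        assert abs(r.p6 - 1.0) < 0.15
        assert abs(r.p8) < 0.15
        assert abs(r.c_S_uM - 10.0) / 10.0 < 0.02
        assert abs(r.c_ES_uM - 1.5) / 1.5 < 0.05


class TestUnmixSeries:
    def test_identical_spectra_give_constant_traces(self, refs):
        specs = [Spectrum(refs.common_grid,
                          mixture(refs, c_S=5.0, c_ES=1.0).absorbance,
                          time_s=5.0 * i) for i in range(6)]
        series = unmix_series(specs, refs)
        assert np.ptp(series.c_S_uM) < 1e-8
        assert np.ptp(series.c_ES_uM) < 1e-8

    def test_empty_list_rejected(self, refs):
        with pytest.raises(InvalidInputError):
            unmix_series([], refs)

    def test_preincubation_series_recovers_binding_course(self, clean_noise):
        # ES rises, S falls, P stays zero during the no-donor stage
        exp = generate_experiment(
            get_scenario("preincubation", noise=clean_noise), seed=3)
        specs = exp.stage_spectra(0)
        series = unmix_series(specs, exp.refs)
        assert series.c_ES_uM[-1] > series.c_ES_uM[0]
        assert series.c_S_uM[-1] < series.c_S_uM[0]
        assert np.max(series.c_P_uM) < 1e-6
        # and the traces match the simulator's ground truth pointwise
        t_match = np.isin(exp.truth.time_s, series.time_s)
        np.testing.assert_allclose(series.c_ES_uM,
                                   exp.truth.c_ES[t_match], atol=1e-6)


class TestConservationCheck:
    def test_noise_free_turnover_series_conserves_total(self, clean_noise):
        exp = generate_experiment(
            get_scenario("pchlide_initiated", noise=clean_noise), seed=3)
        series = unmix_series(list(exp.spectra), exp.refs)
        report = conservation_check(series, 20.0, rel_tol=1e-6)
        assert report.passed, str(report)

    def test_corrupted_point_fails_check(self, refs):
        # one spectrum loses its product band while truth had product
        good = mixture(refs, c_S=10.0, c_P=5.0)
        bad = mixture(refs, c_S=10.0, c_P=0.0)
        specs = [Spectrum(refs.common_grid, s.absorbance, time_s=t)
                 for t, s in [(0.0, good), (5.0, bad), (10.0, good)]]
        series = unmix_series(specs, refs)
        report = conservation_check(series, 15.0, rel_tol=1e-3)
        assert not report.passed
        assert report.worst_time_s == 5.0

    def test_single_point_at_expected_total_passes(self, refs):
        spec = mixture(refs, c_S=15.0)
        series = unmix_series([spec], refs)
        assert conservation_check(series, 15.0, rel_tol=1e-6).passed
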