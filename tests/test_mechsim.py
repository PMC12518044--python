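import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dporkin.errors import InvalidInputError
from dporkin.kinfit import fit_one_phase, fit_two_phase
from dporkin.mechsim import (MechanismParams, SitePool, Stage,
                             binding_site_capacity, equilibrium_es,
                             pseudo_first_order_kobs, simulate,
                             simulate_event_sequence)

T600 = np.arange(0.0, 601.0, 5.0)


class TestSimulateBasics:
    def test_all_rate_constants_zero_gives_constant_trajectory(self):
        p = MechanismParams(k_on=0.0, E_total_uM=1.0, S_total_uM=20.0)
        tr = simulate(p, T600)
        np.testing.assert_allclose(tr.c_S, 20.0)
        np.testing.assert_allclose(tr.c_ES, 0.0)
        np.testing.assert_allclose(tr.c_P, 0.0)

    def test_pseudo_first_order_closed_form(self):
        # S >> E, no catalysis: ES(t) = E*(1 - exp(-k_on*S*t)) within 1%
        p = MechanismParams(k_on=0.023 / 20, E_total_uM=1.0, S_total_uM=20.0)
        tr = simulate(p, T600)
        closed = 1.0 * (1 - np.exp(-0.023 * tr.time_s))
        assert np.max(np.abs(tr.c_ES - closed)) < 0.01 * 1.0

    def test_rapid_turnover_limit_keeps_es_empty(self):
        # k_cat -> infinity: product forms at the encounter rate, ES ~ 0
        p = MechanismParams(k_on=1.0, E_total_uM=1.0, S_total_uM=5.0,
                            k_cat=1e6)
        t = np.linspace(0.0, 3.0, 40)
        tr = simulate(p, t)
        assert np.max(tr.c_ES) < 1e-4
        # reduced one-step model: dS/dt = -k_on*E*S with E ~ E_total
        reduced = 5.0 * np.exp(-1.0 * 1.0 * t)
        np.testing.assert_allclose(tr.c_S, reduced, rtol=0.02, atol=1e-3)

    def test_bad_time_grid_rejected(self):
        p = MechanismParams(k_on=0.001, E_total_uM=1.0, S_total_uM=20.0)
        with pytest.raises(InvalidInputError):
            simulate(p, np.array([5.0, 10.0]))  # does not start at 0
        with pytest.raises(InvalidInputError):
            simulate(p, np.array([0.0, 10.0, 10.0]))


class TestConservation:
    @pytest.mark.parametrize("release", [True, False])
    def test_mass_conserved_single_pool(self, release):
        p = MechanismParams(k_on=0.01, k_off=0.002, k_cat=0.005,
                            E_total_uM=2.0, S_total_uM=20.0,
                            release_product=release)
        tr = simulate(p, T600)
        np.testing.assert_allclose(tr.total_pchlide(), 20.0, rtol=1e-9)

    def test_mass_and_sites_conserved_two_site(self):
        p = MechanismParams(k_on=0.0, E_total_uM=4.0, S_total_uM=20.0,
                            site_model="two_site", k_on1=9e-4, k_off1=1e-4,
                            k_on2=1.1e-4, k_off2=1e-5, k_cat=0.01,
                            release_product=False)
        tr = simulate(p, T600)
        np.testing.assert_allclose(tr.total_pchlide(), 20.0, rtol=1e-9)

    def test_monotonicity(self):
        p = MechanismParams(k_on=0.001, k_cat=0.004, E_total_uM=1.0,
                            S_total_uM=20.0)
        tr = simulate(p, T600)
        assert np.all(np.diff(tr.c_P) >= -1e-12)
        # binding-only from empty sites: ES nondecreasing
        p0 = MechanismParams(k_on=0.001, E_total_uM=1.0, S_total_uM=20.0)
        tr0 = simulate(p0, T600)
        assert np.all(np.diff(tr0.c_ES) >= -1e-12)

    def test_equilibrium_matches_quadratic_closed_form(self):
        # k_cat = 0: long-time ES equals the Kd binding quadratic root
        kon, koff = 0.01, 0.05
        p = MechanismParams(k_on=kon, k_off=koff, E_total_uM=2.0,
                            S_total_uM=10.0)
        t = np.array([0.0, 5e3, 1e4])
        tr = simulate(p, t)
        expected = equilibrium_es(2.0, 10.0, koff / kon)
        np.testing.assert_allclose(tr.c_ES[-1], expected, rtol=1e-6)


class TestPools:
    def test_two_pool_product_matches_two_phase_closed_form(self):
        # saturated sites, no release: P(t) is exactly the two-phase form
        # with spans = pool site amounts and rates = pool k_cat
        kf, ks = 0.004, 0.0006
        p = MechanismParams(k_on=10.0, E_total_uM=1.0, S_total_uM=20.0,
                            pools=(SitePool(0.5, kf), SitePool(0.5, ks)),
                            release_product=False)
        t = np.arange(0.0, 1201.0, 5.0)
        tr = simulate(p, t)
        closed = (0.5 * (1 - np.exp(-kf * t)) + 0.5 * (1 - np.exp(-ks * t)))
        # sites fill within ~0.05 s at k_on*S = 200/s, so the closed form
        # applies essentially from t=0
        assert np.max(np.abs(tr.c_P - closed)) < 2e-3
        fit = fit_two_phase(t[1:], tr.c_P[1:])
        np.testing.assert_allclose(fit.params["k_fast"], kf, rtol=0.02)
        np.testing.assert_allclose(fit.params["k_slow"], ks, rtol=0.02)

    def test_pool_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            MechanismParams(k_on=0.001, E_total_uM=1.0, S_total_uM=20.0,
                            pools=(SitePool(0.5), SitePool(0.7)))


class TestKobs:
    def test_arithmetic(self):
        p = MechanismParams(k_on=0.023 / 20, E_total_uM=1.0, S_total_uM=20.0)
        np.testing.assert_allclose(pseudo_first_order_kobs(p), 0.023)
        p2 = MechanismParams(k_on=0.0, k_off=0.7, E_total_uM=1.0,
                             S_total_uM=20.0)
        assert pseudo_first_order_kobs(p2) == 0.7

    def test_agrees_with_simulated_one_phase_fit(self):
        # cross-module oracle: simulate S >> E, fit, compare with kobs
        p = MechanismParams(k_on=0.023 / 40, E_total_uM=1.0, S_total_uM=40.0)
        tr = simulate(p, T600)
        fit = fit_one_phase(tr.time_s[1:], tr.c_ES[1:])
        np.testing.assert_allclose(fit.params["k"], pseudo_first_order_kobs(p),
                                   rtol=0.02)


class TestEventSequence:
    def _binding(self, **kw):
        return MechanismParams(k_on=0.023 / 20, E_total_uM=1.0,
                               S_total_uM=20.0, **kw)

    def test_no_product_without_donor_stage(self):
        stages = [Stage(600.0, self._binding()),
                  Stage(600.0, self._binding(k_cat=0.004,
                                             release_product=False))]
        tr = simulate_event_sequence(stages, 5.0)
        in_stage1 = tr.time_s <= 600.0
        assert np.all(tr.c_P[in_stage1] == 0.0)
        assert tr.c_P[-1] > 0.1

    def test_substrate_injection_steps_only_substrate(self):
        empty = MechanismParams(k_on=0.0, E_total_uM=1.0, S_total_uM=0.0)
        stages = [Stage(10.0, empty),
                  Stage(10.0, empty, inject_S_uM=20.0)]
        tr = simulate_event_sequence(stages, 5.0)
        assert tr.c_S[0] == 0.0
        assert tr.c_S[-1] == 20.0
        assert np.all(tr.c_ES == 0.0)

    def test_identical_stages_equal_single_run(self):
        p = self._binding()
        two = simulate_event_sequence([Stage(300.0, p), Stage(300.0, p)], 5.0)
        one = simulate(p, T600)
        np.testing.assert_allclose(two.c_ES, one.c_ES, atol=1e-9)
        np.testing.assert_allclose(two.time_s, one.time_s)

    def test_negative_injection_rejected(self):
        with pytest.raises(InvalidInputError):
            Stage(10.0, self._binding(), inject_S_uM=-1.0)


class TestSiteCapacity:
    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_two_sites_per_tetramer(self, bchnb):
        assert binding_site_capacity(bchnb) == 2 * bchnb
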