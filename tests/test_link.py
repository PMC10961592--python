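"""Effect-compartment kinetics, link fitting and hysteresis loops."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mdpkpd import (EffectSeries, LinkParams, PdParams, SampleSeries,
                    classify_relationship, effect_compartment_conc, fit_link,
                    fit_pk, hysteresis_loop, pd_predict, predict_conc)
from mdpkpd.errors import InsufficientDataError, UnidentifiableError
from conftest import DOSE, INTERVAL


class TestEffectCompartment:
    def test_fast_equilibration_tracks_plasma(self, bateman_truth, grid_mid):
        cp = predict_conc(bateman_truth, grid_mid, DOSE)
        ce = effect_compartment_conc(bateman_truth, 1e6 * 0.05, grid_mid, DOSE)
        assert np.allclose(ce, cp, rtol=1e-3)

    def test_matches_ode_integrator(self, bateman_truth):
        ke0 = 0.02

        def rhs(t, y):
            cp = predict_conc(bateman_truth, [t], DOSE)[0]
            return [ke0 * (cp - y[0])]

        t_eval = np.linspace(5.0, 480.0, 48)
        sol = solve_ivp(rhs, (0, 480), [0.0], t_eval=t_eval,
                        rtol=1e-11, atol=1e-13)
        got = effect_compartment_conc(bateman_truth, ke0, t_eval, DOSE)
        assert np.allclose(got, sol.y[0], rtol=1e-6)

    def test_effect_site_peak_lags_plasma_peak(self, bateman_truth):
        t = np.arange(0, 480, 0.1)
        cp = predict_conc(bateman_truth, t, DOSE)
        ce = effect_compartment_conc(bateman_truth, 0.02, t, DOSE)
        assert t[np.argmax(ce)] > t[np.argmax(cp)]

    def test_rate_equal_to_ke0_limit_is_continuous(self, bateman_truth):
        t = np.arange(10, 480, 20.0)
        at = effect_compartment_conc(bateman_truth, bateman_truth.ke, t, DOSE)
        near = effect_compartment_conc(bateman_truth,
                                       bateman_truth.ke * (1 + 1e-7), t, DOSE)
        assert np.allclose(at, near, rtol=1e-4)


class TestFitLink:
    TRUTH = LinkParams(ke0=0.02,
                       pd=PdParams(100.0, 60.0, 15.0, 1.5, "stimulation"))

    def _effect_series(self, grid_mid, bateman_truth):
        ce = effect_compartment_conc(bateman_truth, self.TRUTH.ke0,
                                     grid_mid, DOSE)
        return EffectSeries("Tau", grid_mid, pd_predict(self.TRUTH.pd, ce),
                            100.0)

    def test_noise_free_recovery_within_5pct(self, grid_mid, bateman_truth,
                                             clean_interval_series):
        pk_fit = fit_pk(clean_interval_series, "1C", dose=DOSE, seed=0)
        lf = fit_link(clean_interval_series,
                      self._effect_series(grid_mid, bateman_truth),
                      pk_fit, "stimulation")
        assert lf.params.ke0 == pytest.approx(0.02, rel=0.05)
        assert lf.params.pd.e0 == pytest.approx(100.0, rel=0.05)
        assert lf.params.pd.emax_or_imax == pytest.approx(60.0, rel=0.05)
        assert lf.params.pd.c50 == pytest.approx(15.0, rel=0.05)
        assert lf.params.pd.hill_n == pytest.approx(1.5, rel=0.05)

    def test_direct_effect_limit_has_no_loop(self, grid_mid, bateman_truth,
                                             clean_interval_series):
        # generated with near-instant equilibration: the fitted effect vs
        # plasma concentration trajectory should not loop
        truth = LinkParams(ke0=10.0,
                           pd=PdParams(100.0, 60.0, 15.0, 1.5, "stimulation"))
        ce = effect_compartment_conc(bateman_truth, truth.ke0, grid_mid, DOSE)
        eff = EffectSeries("Tau", grid_mid, pd_predict(truth.pd, ce), 100.0)
        pk_fit = fit_pk(clean_interval_series, "1C", dose=DOSE, seed=0)
        lf = fit_link(clean_interval_series, eff, pk_fit, "stimulation")
        # evaluate the fitted trajectory densely: the 20-min polygon keeps a
        # curvature sliver even for a strictly single-valued relation
        t_dense = np.arange(1.0, 480.0, 2.0)
        cp = predict_conc(bateman_truth, t_dense, DOSE)
        ce_fit = effect_compartment_conc(pk_fit.params, lf.params.ke0,
                                         t_dense, DOSE)
        loop = hysteresis_loop(cp, pd_predict(lf.params.pd, ce_fit), t_dense)
        assert abs(loop.normalized_area) < 0.02

    def test_flat_effect_unidentifiable(self, grid_mid, bateman_truth,
                                        clean_interval_series):
        pk_fit = fit_pk(clean_interval_series, "1C", dose=DOSE, seed=0)
        flat = EffectSeries("Tau", grid_mid, np.full(grid_mid.size, 100.0),
                            100.0)
        with pytest.raises(UnidentifiableError):
            fit_link(clean_interval_series, flat, pk_fit, "stimulation")


class TestHysteresisLoop:
    SQUARE = ([0.0, 1.0, 1.0, 0.0], [0.0, 0.0, 1.0, 1.0])

    def test_unit_square_counterclockwise(self):
        res = hysteresis_loop(*self.SQUARE)
        assert res.signed_area == pytest.approx(1.0)
        assert res.normalized_area == pytest.approx(1.0)
        assert res.direction == "counterclockwise"

    def test_reversed_square_clockwise(self):
        res = hysteresis_loop(self.SQUARE[0][::-1], self.SQUARE[1][::-1])
        assert res.signed_area == pytest.approx(-1.0)
        assert res.direction == "clockwise"

    def test_single_valued_relation_has_no_loop(self):
        c = np.concatenate([np.linspace(0, 50, 12), np.linspace(50, 0, 12)])
        e = 100 + 0.8 * c  # effect a strict function of concentration
        res = hysteresis_loop(c, e)
        assert abs(res.normalized_area) < 0.01
        assert res.direction == "none"

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            hysteresis_loop([0, 1, 2], [0, 1, 0])

    def test_degenerate_range_is_none(self):
        res = hysteresis_loop([5, 5, 5, 5], [0, 1, 2, 1])
        assert res.direction == "none"

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 200)),
                    min_size=4, max_size=20))
    def test_time_reversal_flips_sign(self, pts):
        c = np.array([p[0] for p in pts])
        e = np.array([p[1] for p in pts])
        fwd = hysteresis_loop(c, e)
        rev = hysteresis_loop(c[::-1], e[::-1])
        assert rev.signed_area == pytest.approx(-fwd.signed_area, abs=1e-9)
        assert abs(fwd.normalized_area) <= 1.0 + 1e-12

    def test_open_loop_flagged(self):
        res = hysteresis_loop([0, 10, 20, 30], [100, 120, 140, 160])
        assert res.open_loop


class TestClassifyRelationship:
    def _res(self, direction):
        from mdpkpd.link import HysteresisResult
        sign = {"clockwise": -0.5, "counterclockwise": 0.5, "none": 0.0}
        return HysteresisResult(sign[direction], sign[direction], direction, 24)

    def test_inhibitory_clockwise_is_delayed_suppression(self):
        assert classify_relationship(self._res("clockwise"), "inhibition") \
            == "delayed suppression (Asp/Glu pattern)"

    def test_stimulatory_counterclockwise_is_delayed_enhancement(self):
        assert classify_relationship(self._res("counterclockwise"),
                                     "stimulation") \
            == "delayed enhancement (Tau/Ach pattern)"

    @pytest.mark.parametrize("mode", ["stimulation", "inhibition"])
    def test_no_loop_is_atypical(self, mode):
        assert classify_relationship(self._res("none"), mode) == "atypical"

    def test_mismatched_direction_is_atypical(self):
        assert classify_relationship(self._res("clockwise"), "stimulation") \
            == "atypical"


def test_simulated_loop_directions_match_modes(bateman_truth, grid_mid):
    """Finite-ke0 stimulation loops run counterclockwise and inhibition
    loops clockwise against the plasma concentration."""
    cp = predict_conc(bateman_truth, grid_mid, DOSE)
    ce = effect_compartment_conc(bateman_truth, 0.02, grid_mid, DOSE)
    stim = pd_predict(PdParams(100.0, 60.0, 15.0, 1.5, "stimulation"), ce)
    inhib = pd_predict(PdParams(100.0, 0.4, 15.0, 1.5, "inhibition"), ce)
    assert hysteresis_loop(cp, stim, grid_mid).direction == "counterclockwise"
    assert hysteresis_loop(cp, inhib, grid_mid).direction == "clockwise"
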