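import math

import numpy as np
import pytest
import scipy.linalg as sla
import scipy.optimize as sopt

from helpers import joint_gaussian_loglik
from wearssm.datamodel_io import Channel, MealEvent, ParticipantRecord, SensorSeries
from wearssm.glucose_model import (
    GlucoseParams,
    _expm_2x2,
    circadian_baseline,
    cosinor_fit,
    damping_coefficient,
    half_life,
    impulse_shape,
    meal_response,
    model1_loglik,
    model1_param_model,
    observation_mean,
    response_peak,
)
from wearssm.ssm_core import stationary_covariance, transitions_for_times


def _params(**kw):
    base = dict(
        A11=1.0, A12=0.7, A21=0.7, A22=1.0, B22=0.3, sigma=0.25, A0=4.5,
        A1=0.8, phi=15.0, heights={"m": 1.0},
    )
    base.update(kw)
    return GlucoseParams(**base)


def _tiny_record(times, values, meals=()):
    horizon = float(times[-1]) + 0.25
    return ParticipantRecord(
        "t",
        {Channel.GLUCOSE: SensorSeries(Channel.GLUCOSE, times, values)},
        list(meals),
        (0.0, horizon),
    )


class TestImpulseShape:
    @pytest.mark.parametrize(
        "W",
        [
            np.array([[-1.0, -1.5], [1.2, -0.8]]),  # underdamped
            np.array([[-1.0, -0.1], [0.5, -3.0]]),  # overdamped
            np.array([[-1.5, -0.5], [0.5, -0.5]]),  # critically damped
        ],
    )
    def test_matches_matrix_exponential(self, W):
        taus = np.linspace(0.0, 6.0, 25)
        expected = np.array([sla.expm(W * t)[1, 0] for t in taus])
        np.testing.assert_allclose(impulse_shape(W, taus), expected, atol=1e-12)
        for t in (0.1, 0.9, 3.3):
            np.testing.assert_allclose(_expm_2x2(W, t), sla.expm(W * t), atol=1e-12)

    def test_peak_matches_grid_argmax(self):
        W = np.array([[-1.0, -1.5], [1.2, -0.8]])
        t_peak, peak = response_peak(W)
        taus = np.linspace(0, 10, 200001)
        s = impulse_shape(W, taus)
        assert t_peak == pytest.approx(taus[np.argmax(s)], abs=1e-4)
        assert peak == pytest.approx(s.max(), rel=1e-8)


class TestMealResponse:
    def test_no_meals_zero(self):
        p = _params()
        t = np.linspace(0, 48, 100)
        np.testing.assert_array_equal(meal_response(p, [], t), 0.0)

    def test_peak_equals_height(self):
        p = _params(heights={"m": 1.2})
        t = np.linspace(0, 72, 100001)
        r = meal_response(p, [MealEvent(2.0, "m")], t)
        assert r.max() == pytest.approx(1.2, abs=1e-6)
        assert np.all(r[t < 2.0] == 0.0)

    def test_translation_invariance_when_decayed(self):
        # two identical meals 48 h apart: the response after meal 2 equals
        # the response after meal 1 shifted (rates >= 0.5/h decay fully)
        p = _params(A11=1.0, A12=0.5, A21=0.5, A22=1.0, heights={"m": 1.0})
        t = np.arange(0, 96, 0.01)
        r = meal_response(p, [MealEvent(1.0, "m"), MealEvent(49.0, "m")], t)
        seg1 = r[(t >= 1.0) & (t < 25.0)]
        seg2 = r[(t >= 49.0) & (t < 73.0)]
        np.testing.assert_allclose(seg2, seg1, atol=1e-9)

    def test_linear_superposition(self):
        p = _params(heights={"a": 0.9, "b": 1.4})
        t = np.arange(0, 48, 0.05)
        ev_a, ev_b = MealEvent(3.0, "a"), MealEvent(7.5, "b")
        both = meal_response(p, [ev_a, ev_b], t)
        np.testing.assert_allclose(
            both, meal_response(p, [ev_a], t) + meal_response(p, [ev_b], t), atol=1e-12
        )

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            meal_response(_params(), [MealEvent(1.0, "nope")], np.linspace(0, 10, 5))

    def test_deterministic(self):
        p = _params()
        t = np.arange(0, 24, 0.25)
        r1 = meal_response(p, [MealEvent(6.0, "m")], t)
        r2 = meal_response(p, [MealEvent(6.0, "m")], t)
        np.testing.assert_array_equal(r1, r2)


class TestCircadian:
    def test_peak_value(self):
        assert circadian_baseline(4.0, 1.0, 15.0, np.array([15.0]))[0] == pytest.approx(5.0)

    def test_trough_value(self):
        assert circadian_baseline(4.0, 1.0, 15.0, np.array([3.0]))[0] == pytest.approx(4.0)

    def test_mean_over_day(self):
        t = np.arange(0, 24, 1e-3)
        g = circadian_baseline(4.0, 1.0, 15.0, t)
        assert np.mean(g) == pytest.approx(4.5, abs=1e-6)

    def test_periodicity(self):
        t = np.array([1.0, 7.3, 18.2])
        np.testing.assert_allclose(
            circadian_baseline(4, 1, 15, t), circadian_baseline(4, 1, 15, t + 24.0)
        )


class TestDamping:
    def test_overdamped_example(self):
        assert damping_coefficient(np.diag([-1.0, -3.0])) == pytest.approx(0.25)

    def test_underdamped_example(self):
        W = np.array([[-1.0, -1.0], [1.0, -1.0]])
        assert damping_coefficient(W) == pytest.approx(-1.0)

    def test_critical_example(self):
        W = np.array([[-1.0, 1.0], [0.0, -1.0]])
        assert damping_coefficient(W) == pytest.approx(0.0, abs=1e-12)

    def test_traceless_undefined(self):
        with pytest.raises(ValueError):
            damping_coefficient(np.array([[1.0, 0.0], [0.0, -1.0]]))

    def test_sign_matches_eigen_discriminant(self, rng):
        for _ in range(300):
            A = np.abs(rng.normal(0.2, 1.0, 4)) + 1e-3
            W = np.array([[-A[0], -A[1]], [A[2], -A[3]]])
            dc = damping_coefficient(W)
            eig = np.linalg.eigvals(W)
            if abs(dc) > 1e-12:
                assert (dc < 0) == bool(np.iscomplex(eig).any())


class TestHalfLife:
    def test_single_exponential_limit(self):
        # x1 relaxes ~200x faster than x2: post-peak decay is e^{-k t}
        k = 0.5
        p = _params(A11=100.0, A12=0.01, A21=0.01, A22=k)
        assert half_life(p) == pytest.approx(math.log(2) / k, rel=0.01)

    def test_time_rescaling(self):
        p = _params()
        p2 = _params(A11=2 * p.A11, A12=2 * p.A12, A21=2 * p.A21, A22=2 * p.A22)
        assert half_life(p2) == pytest.approx(half_life(p) / 2.0, rel=1e-6)

    def test_critically_damped_closed_form(self):
        # shape t e^{-a t} with a = 1: peak at t = 1; crossing of half the
        # peak value found independently by fine-grid bisection
        p = _params(A11=1.5, A12=0.5, A21=0.5, A22=0.5, heights={"m": 1.0})
        W = p.W
        assert damping_coefficient(W) == pytest.approx(0.0, abs=1e-10)
        t_peak, peak = response_peak(W)
        assert t_peak == pytest.approx(1.0, abs=1e-9)
        f = lambda t: t * math.exp(-t) - 0.5 * math.exp(-1.0)
        oracle = sopt.bisect(f, 1.0, 10.0, xtol=1e-10) - 1.0
        assert oracle == pytest.approx(1.678, abs=1e-3)
        assert half_life(p) == pytest.approx(oracle, abs=1e-6)


class TestModel1Loglik:
    def test_noise_free_residuals(self, rng):
        # B22 = 0 and sigma fixed: the model is iid noise around r + g
        t = np.arange(0, 48, 0.5)
        p = _params(B22=1e-12)
        meals = [MealEvent(8.0, "m"), MealEvent(20.0, "m")]
        m = observation_mean(p, meals, t)
        y = m + rng.normal(0, p.sigma, t.size)
        rec = _tiny_record(t, np.maximum(y, 0.1), meals)
        ll = model1_loglik(p, rec)
        resid = rec.glucose.values - m
        iid = np.sum(
            -0.5 * (np.log(2 * np.pi * p.sigma**2) + resid**2 / p.sigma**2)
        )
        assert ll == pytest.approx(iid, abs=1e-6)

    def test_large_sigma_iid_limit(self):
        t = np.arange(0, 24, 0.5)
        y = np.full(t.size, 5.0)
        p = _params(sigma=50.0, A1=0.0, A0=5.0, B22=0.01, heights={})
        rec = _tiny_record(t, y)
        ll = model1_loglik(p, rec)
        iid = t.size * (-0.5 * math.log(2 * math.pi * 50.0**2))
        assert ll == pytest.approx(iid, rel=1e-4)

    def test_matches_joint_gaussian_oracle(self, rng):
        t = np.cumsum(rng.uniform(0.2, 0.5, 8))
        p = _params()
        meals = [MealEvent(float(t[1]), "m")]
        y = 4.5 + rng.normal(0, 0.5, 8)
        rec = _tiny_record(t, y, meals)
        ll = model1_loglik(p, rec)
        sys = p.system()
        Fs, Qs = transitions_for_times(sys, t)
        m = observation_mean(p, meals, t)
        specs = [(np.array([[0.0, 1.0]]), [m[k]], [[p.sigma**2]]) for k in range(8)]
        oracle = joint_gaussian_loglik(
            Fs, Qs, specs, list(y), np.zeros(2), stationary_covariance(sys)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_fast_path_matches_generic(self, standard_record):
        record, _ = standard_record
        model = model1_param_model(record)
        theta = model.init_theta()
        fast = model.loglik_fn(theta)
        generic = model1_loglik(model.to_params(theta), record)
        assert fast == pytest.approx(generic, abs=2e-6)

    def test_fast_path_irregular_grid_and_perturbed_theta(self, standard_record, rng):
        record, _ = standard_record
        # random subset -> irregular sampling intervals
        g = record.glucose
        keep = np.sort(rng.choice(len(g), size=len(g) // 2, replace=False))
        rec2 = ParticipantRecord(
            "sub",
            {Channel.GLUCOSE: SensorSeries(Channel.GLUCOSE, g.times[keep], g.values[keep])},
            record.meals,
            record.window,
        )
        model = model1_param_model(rec2)
        for _ in range(5):
            theta = model.init_theta() * np.exp(rng.normal(0, 0.2, model.k))
            fast = model.loglik_fn(theta)
            generic = model1_loglik(model.to_params(theta), rec2)
            assert fast == pytest.approx(generic, abs=2e-6)

    def test_circadian_nesting(self, standard_record):
        record, _ = standard_record
        full = model1_param_model(record)
        reduced = model1_param_model(record, include_circadian=False)
        assert reduced.k == full.k - 2
        theta_full = full.init_theta()
        theta_full[7] = 1e-300  # A1 -> 0 (positive for the log transform)
        theta_red = np.delete(theta_full, [7, 8])
        assert full.loglik_fn(theta_full) == pytest.approx(
            reduced.loglik_fn(theta_red), abs=1e-8
        )


class TestCosinor:
    def test_recovers_pure_sinusoid(self):
        t = np.arange(0, 72, 0.25)
        y = circadian_baseline(4.0, 1.2, 16.0, t)
        mesor, amp, phase = cosinor_fit(t, y)
        assert mesor == pytest.approx(4.6, abs=1e-9)
        assert amp == pytest.approx(1.2, abs=1e-9)
        assert phase == pytest.approx(16.0, abs=1e-9)
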