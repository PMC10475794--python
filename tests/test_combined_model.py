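import dataclasses

import numpy as np
import pytest

from helpers import joint_gaussian_loglik
from wearssm.combined_model import (
    CombinedParams,
    build_combined_system,
    cross_correlation,
    glucose_marginal_loglik,
    glucose_variance_decomposition,
    model3_loglik,
    model3_param_model,
    observation_means,
    prepare_combined_data,
    single_input_variant,
    weighted_aux_sum,
    H_COMBINED,
)
from wearssm.cardio_model import prepare_cardio_data
from wearssm.datamodel_io import Channel
from wearssm.glucose_model import model1_loglik
from wearssm.inference import HMCConfig
from wearssm.ssm_core import stationary_covariance, transitions_for_times
from wearssm.synthetic import (
    default_cardio_params,
    default_scenario,
    generate_participant,
    midrange_glucose_params,
)


def _combined(c51=0.0, c52=0.0, c53=0.0):
    return CombinedParams(
        cardio=default_cardio_params(),
        glucose=midrange_glucose_params(),
        C51=c51, C52=c52, C53=c53,
    )


def _small_dataset(seed=3, couplings=(0.0, 0.0, 0.0), days=4.0, step=30):
    spec = default_scenario(seed=seed)
    params = dataclasses.replace(
        spec.params, C51=couplings[0], C52=couplings[1], C53=couplings[2]
    )
    spec = dataclasses.replace(
        spec, params=params, duration_days=days, cgm_step_min=step, aux_step_min=step
    )
    record, truth = generate_participant(spec)
    data = prepare_combined_data(record, prepare_cardio_data(record))
    return record, data, params


class TestSystemAssembly:
    def test_coupling_placement(self):
        p = _combined(0.5, -0.2, 0.1)
        W = p.W
        np.testing.assert_array_equal(W[4, :3], [0.5, -0.2, 0.1])
        assert np.all(W[3, :3] == 0.0)
        assert np.all(W[:3, 3:] == 0.0)

    def test_stable_for_any_couplings(self, rng):
        # W is block lower-triangular, so couplings of any magnitude
        # cannot destabilize it; the assembly check must accept these
        for _ in range(10):
            c = rng.normal(0, 20, 3)
            sys = build_combined_system(_combined(*c))
            assert sys.stable

    def test_steady_state_shift(self):
        # with constant aux states a, the deterministic glucose steady
        # state solves the 2x2 glucose block against the weighted input
        p = _combined(-0.3, 0.4, 0.1)
        a = np.array([1.0, 2.0, -1.0])
        u = float(p.couplings @ a)
        g = p.glucose
        A = np.array([[-g.A11, -g.A12], [g.A21, -g.A22]])
        xg = np.linalg.solve(A, -np.array([0.0, u]))
        x = np.concatenate([a, xg])
        resid = p.W @ x
        np.testing.assert_allclose(resid[3:], 0.0, atol=1e-12)

    def test_nesting_reproduces_model1(self, short_record):
        record, _ = short_record
        data = prepare_combined_data(record, prepare_cardio_data(record))
        p = _combined()
        assert glucose_marginal_loglik(p, data) == pytest.approx(
            model1_loglik(p.glucose, record), abs=1e-8
        )

    def test_matches_5d_joint_gaussian_oracle(self, rng):
        _, data, params = _small_dataset(seed=5, couplings=(-0.3, 0.4, 0.0))
        sl = slice(0, 5)
        times = data.times[sl]
        sys = build_combined_system(params)
        ll_mask = np.zeros_like(data.mask)
        ll_mask[sl] = data.mask[sl]
        small = dataclasses.replace(
            data, times=times, y=data.y[sl], mask=data.mask[sl],
            meals=[m for m in data.meals if m.time <= times[-1]],
        )
        ll = model3_loglik(params, small)
        Fs, Qs = transitions_for_times(sys, times)
        m = observation_means(params, small)
        sig2 = np.concatenate([params.cardio.sigma_vec() ** 2, [params.glucose.sigma**2]])
        specs, ys = [], []
        for k in range(times.size):
            rows = np.flatnonzero(small.mask[k])
            specs.append((H_COMBINED[rows], m[k, rows], np.diag(sig2[rows])))
            ys.append(small.y[k, rows])
        oracle = joint_gaussian_loglik(
            Fs, Qs, specs, ys, np.zeros(5), stationary_covariance(sys)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestWeightedAuxSum:
    def test_activity_only(self):
        _, data, _ = _small_dataset()
        p = _combined(1.0, 0.0, 0.0)
        s, valid = weighted_aux_sum(p, data)
        np.testing.assert_array_equal(s[data.mask[:, 0]], data.y[data.mask[:, 0], 0])

    def test_zero_couplings(self):
        _, data, _ = _small_dataset()
        s, _ = weighted_aux_sum(_combined(), data)
        np.testing.assert_array_equal(s, 0.0)

    def test_imputation_only_changes_missing(self):
        _, data, params = _small_dataset(seed=9)
        p = dataclasses.replace(params, C51=-0.4, C52=0.3, C53=0.2)
        raw, valid = weighted_aux_sum(p, data, impute=False)
        imp, valid2 = weighted_aux_sum(p, data, impute=True)
        assert np.all(valid2)
        np.testing.assert_allclose(imp[valid], raw[valid], atol=1e-9)
        assert np.any(valid != valid2) or np.all(valid)


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero(self, rng):
        x = rng.normal(size=500)
        lags, corr, best = cross_correlation(x, x, dt=0.25, max_lag=3.0)
        assert best == 0.0
        assert corr[len(lags) // 2] == pytest.approx(1.0)

    def test_shifted_copy_peaks_at_shift(self, rng):
        x = rng.normal(size=800)
        y = np.roll(x, 4)  # y[k] = x[k-4]: y lags x by 4 steps
        lags, corr, best = cross_correlation(x, y, dt=1.0, max_lag=8.0)
        assert best == 4.0

    def test_white_noise_bound(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            _, corr, _ = cross_correlation(
                r.normal(size=1000), r.normal(size=1000), dt=1.0, max_lag=5.0
            )
            if np.nanmax(np.abs(corr)) < 0.15:
                hits += 1
        assert hits >= 18

    def test_sparse_lag_masked(self):
        x = np.arange(10.0)
        v = np.zeros(10, bool)
        v[:3] = True
        _, corr, _ = cross_correlation(x, x, dt=1.0, max_lag=2.0, valid_x=v, valid_y=v)
        assert np.isnan(corr[0]) and np.isnan(corr[-1])


class TestVarianceDecomposition:
    def test_zero_couplings_equal_pair(self):
        _, data, _ = _small_dataset(seed=11)
        out = glucose_variance_decomposition(_combined(), data)
        assert out["ev_with_aux"] == pytest.approx(out["ev_meals_circadian"], abs=1e-6)

    def test_strong_couplings_add_variance(self):
        wins = 0
        for seed in range(10):
            _, data, params = _small_dataset(
                seed=300 + seed, couplings=(-0.8, 1.0, 0.0), days=4.0
            )
            out = glucose_variance_decomposition(params, data)
            if out["ev_with_aux"] > out["ev_meals_circadian"] + 0.05:
                wins += 1
        assert wins >= 9

    def test_perfect_prediction_is_one(self):
        from wearssm.inference import explained_variance

        y = np.random.default_rng(0).normal(size=50)
        ev, _ = explained_variance(y, y)
        assert ev[0] == pytest.approx(1.0)


class TestSingleInputVariants:
    def test_sign_recovery_map(self):
        # MAP sign of the activity coupling with truth C51 = -0.5
        from wearssm.inference import map_estimate

        hits = 0
        n = 10
        for seed in range(n):
            _, data, params = _small_dataset(
                seed=400 + seed, couplings=(-0.5, 0.0, 0.0)
            )
            model = model3_param_model(
                data, params.cardio, glucose_init=params.glucose,
                active_couplings=("C51",), glucose_locked=params.glucose,
            )
            mp = map_estimate(model)
            if mp.theta[0] < 0:
                hits += 1
        assert hits >= n - 1

    def test_null_coupling_ci_covers_zero(self):
        cfg = HMCConfig(stage1_warmup=60, stage1_draws=60, warmup=100, draws=200)
        covered = 0
        n = 6
        for seed in range(n):
            _, data, params = _small_dataset(seed=500 + seed, couplings=(0.0, 0.0, 0.0))
            name, samples, model = single_input_variant(
                data, params.cardio, params.glucose, Channel.ACTIVITY,
                hmc_config=cfg, seed=seed,
            )
            lo, hi = np.percentile(samples.flat()[:, 0], [5, 95])
            if lo <= 0.0 <= hi:
                covered += 1
        assert covered >= n - 1

    def test_nonzero_hr_coupling_recovered(self):
        cfg = HMCConfig(stage1_warmup=60, stage1_draws=60, warmup=100, draws=200)
        _, data, params = _small_dataset(seed=600, couplings=(0.0, 0.8, 0.0), days=6.0)
        name, samples, model = single_input_variant(
            data, params.cardio, params.glucose, Channel.HR, hmc_config=cfg, seed=0,
        )
        assert name == "C52"
        lo, hi = np.percentile(samples.flat()[:, 0], [5, 95])
        assert lo <= 0.8 <= hi


def test_staged_fitting_preserves_cardio(short_record):
    record, _ = short_record
    data = prepare_combined_data(record, prepare_cardio_data(record))
    cardio = default_cardio_params()
    before = repr(cardio)
    model = model3_param_model(
        data, cardio, glucose_init=midrange_glucose_params(),
        glucose_locked=midrange_glucose_params(),
    )
    theta = np.array([0.3, -0.2, 0.1])
    model.loglik_fn(theta)
    assert repr(cardio) == before
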