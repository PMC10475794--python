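"""Model 3: five-dimensional combined model coupling activity, HR and HRV
into glucose dynamics.

The cardio block (Model 2) is locked to fixed parameter values; three
unconstrained coefficients feed the activity/HR/HRV states into the
glucose observable's state equation. Fitting re-estimates the glucose
parameters jointly with the couplings.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from wearssm.cardio_model import (
    CARDIO_CHANNELS,
    CardioData,
    CardioParams,
    build_cardio_system,
    circadian_means,
)
from wearssm.datamodel_io import Channel, ParticipantRecord
from wearssm.glucose_model import (
    GlucoseParams,
    _theta_to_params,
    circadian_baseline,
    meal_response,
    params_to_theta,
)
from wearssm.inference import Normal, ParamModel, ParamSpec, Identity
from wearssm.ssm_core import LTISystem, kalman_filter, kalman_smooth

#: observation matrix: activity, HR, HRV states and the glucose level state
H_COMBINED = np.zeros((4, 5))
H_COMBINED[0, 0] = H_COMBINED[1, 1] = H_COMBINED[2, 2] = H_COMBINED[3, 4] = 1.0

AUX_CHANNELS = CARDIO_CHANNELS
_COUPLING_NAMES = ("C51", "C52", "C53")


@dataclasses.dataclass
class CombinedParams:
    cardio: CardioParams
    glucose: GlucoseParams
    C51: float = 0.0
    C52: float = 0.0
    C53: float = 0.0

    @property
    def couplings(self) -> np.ndarray:
        return np.array([self.C51, self.C52, self.C53])

    @property
    def W(self) -> np.ndarray:
        W = np.zeros((5, 5))
        W[:3, :3] = self.cardio.W
        g = self.glucose
        W[3, 3], W[3, 4] = -g.A11, -g.A12
        W[4, 3], W[4, 4] = g.A21, -g.A22
        W[4, :3] = self.couplings  # aux -> glucose level row
        return W

    @property
    def Q(self) -> np.ndarray:
        Q = np.zeros((5, 5))
        Q[:3, :3] = self.cardio.Q
        Q[4, 4] = self.glucose.B22
        return Q


def build_combined_system(params: CombinedParams) -> LTISystem:
    sys = LTISystem(params.W, params.Q)
    if not sys.stable:
        raise ValueError("assembled combined drift matrix is unstable")
    return sys


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CombinedData:
    """All four channels on the CGM grid (aux aggregated by interval means)."""

    times: np.ndarray
    y: np.ndarray  # (T, 4): act, hr, hrv (normalized), glucose (mmol/L)
    mask: np.ndarray  # (T, 4)
    meals: list
    sds: dict[Channel, float]
    cardio: CardioData

    @property
    def n_obs(self) -> int:
        return int(np.count_nonzero(self.mask))


def _aggregate_to_grid(
    t_src: np.ndarray, v_src: np.ndarray, obs: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of observed source samples within each grid interval
    (t_{k-1}, t_k]; empty intervals are missing."""
    edges = np.concatenate([[grid[0] - (grid[1] - grid[0])], grid]) if grid.size > 1 else np.array([grid[0] - 1.0, grid[0]])
    idx = np.searchsorted(edges, t_src, side="left") - 1
    ok = (idx >= 0) & (idx < grid.size) & obs
    sums = np.bincount(idx[ok], weights=v_src[ok], minlength=grid.size)
    counts = np.bincount(idx[ok], minlength=grid.size)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return np.nan_to_num(vals), counts > 0


def prepare_combined_data(
    record: ParticipantRecord, cardio_data: CardioData, glucose: np.ndarray | None = None
) -> CombinedData:
    """Stack normalized aux channels (aggregated to the CGM grid) with the
    (optionally detrended) glucose series."""
    g = record.glucose
    grid = g.times
    y = np.zeros((grid.size, 4))
    mask = np.zeros((grid.size, 4), dtype=bool)
    for i, ch in enumerate(AUX_CHANNELS):
        vals, got = _aggregate_to_grid(
            cardio_data.times, cardio_data.y[:, i], cardio_data.mask[:, i], grid
        )
        y[:, i], mask[:, i] = vals, got
    gv = g.values if glucose is None else np.asarray(glucose, dtype=float)
    y[:, 3] = np.where(g.observed, gv, 0.0)
    mask[:, 3] = g.observed
    return CombinedData(grid, y, mask, list(record.meals), dict(cardio_data.sds), cardio_data)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def observation_means(params: CombinedParams, data: CombinedData) -> np.ndarray:
    m = np.zeros((data.times.size, 4))
    m[:, :3] = circadian_means(params.cardio, data.times)
    g = params.glucose
    m[:, 3] = meal_response(g, data.meals, data.times) + circadian_baseline(
        g.A0, g.A1, g.phi, data.times
    )
    return m


def _sigma4(params: CombinedParams) -> np.ndarray:
    return np.concatenate([params.cardio.sigma_vec(), [params.glucose.sigma]]) ** 2


def model3_loglik(params: CombinedParams, data: CombinedData, channel_mask: np.ndarray | None = None) -> float:
    """Exact likelihood of the four observed channels.

    ``channel_mask`` (length 4, bool) optionally restricts which channels
    count as observed (e.g. glucose only, for marginal likelihoods).
    """
    mask = data.mask
    if channel_mask is not None:
        mask = mask & np.asarray(channel_mask, dtype=bool)[None, :]
    res = kalman_filter(
        build_combined_system(params),
        data.times,
        data.y,
        mask,
        observation_means(params, data),
        _sigma4(params),
        H_COMBINED,
    )
    return res.loglik


def glucose_marginal_loglik(params: CombinedParams, data: CombinedData) -> float:
    """Likelihood of the glucose channel alone under the combined model."""
    return model3_loglik(params, data, channel_mask=np.array([False, False, False, True]))


# ---------------------------------------------------------------------------
# ParamModel construction (cardio block locked)
# ---------------------------------------------------------------------------


def model3_param_model(
    data: CombinedData,
    cardio_locked: CardioParams,
    glucose_init: GlucoseParams,
    include_circadian: bool = True,
    active_couplings: Sequence[str] = _COUPLING_NAMES,
    glucose_locked: GlucoseParams | None = None,
    priors: dict[str, object] | None = None,
    coupling_prior_sd: float = 1.0,
) -> ParamModel:
    """Model 3 sampler over glucose parameters + coupling coefficients.

    The cardio block stays locked to ``cardio_locked`` (posterior means of
    a Model-2 fit). ``active_couplings`` selects which of C51/C52/C53 are
    free (others pinned at 0, for the single-input variants). Passing
    ``glucose_locked`` freezes the glucose block so only couplings are
    sampled.
    """
    labels = sorted({m.label for m in data.meals})
    sample_glucose = glucose_locked is None
    if sample_glucose:
        glu_specs = _glucose_specs(glucose_init, labels, include_circadian, priors)
    else:
        glu_specs = []
    specs = list(glu_specs)
    for name in _COUPLING_NAMES:
        if name in active_couplings:
            specs.append(ParamSpec(name, Normal(0.0, coupling_prior_sd), Identity(), 0.0))
    n_glu = len(glu_specs)

    def to_params(theta: np.ndarray) -> CombinedParams:
        if sample_glucose:
            gp = _theta_to_params(theta[:n_glu], labels, include_circadian)
        else:
            gp = glucose_locked
        cvals = {n: 0.0 for n in _COUPLING_NAMES}
        j = n_glu
        for name in _COUPLING_NAMES:
            if name in active_couplings:
                cvals[name] = float(theta[j])
                j += 1
        return CombinedParams(cardio=cardio_locked, glucose=gp, **cvals)

    if sample_glucose:
        def loglik(theta: np.ndarray) -> float:
            return model3_loglik(to_params(theta), data)
    else:
        # observation means do not depend on the couplings: cache them
        m_fixed = observation_means(
            CombinedParams(cardio=cardio_locked, glucose=glucose_locked), data
        )
        sig2 = _sigma4(CombinedParams(cardio=cardio_locked, glucose=glucose_locked))

        def loglik(theta: np.ndarray) -> float:
            p = to_params(theta)
            res = kalman_filter(
                build_combined_system(p), data.times, data.y, data.mask,
                m_fixed, sig2, H_COMBINED,
            )
            return res.loglik

    model = ParamModel(specs, loglik)
    model.to_params = to_params  # type: ignore[attr-defined]
    model.labels = labels  # type: ignore[attr-defined]
    return model


def _glucose_specs(init, labels, include_circadian, priors):
    from wearssm.glucose_model import _SCALAR_ORDER
    from wearssm.inference import Flat, HalfNormal, Log, LogNormal, Normal as N

    prior_map = {
        "A11": LogNormal(0.5, 1.0),
        "A12": LogNormal(0.5, 1.0),
        "A21": LogNormal(0.5, 1.0),
        "A22": LogNormal(0.5, 1.0),
        "B22": HalfNormal(2.0),
        "sigma": HalfNormal(2.0),
        "A0": N(5.0, 3.0),
        "A1": HalfNormal(2.0),
        "phi": Flat(),
    }
    if priors:
        prior_map.update(priors)
    scalar = _SCALAR_ORDER[:9] if include_circadian else _SCALAR_ORDER[:7]
    theta0 = params_to_theta(init, labels, include_circadian)
    specs = []
    for i, name in enumerate(scalar):
        tr = Log() if name not in ("A0", "phi") else Identity()
        specs.append(ParamSpec(name, prior_map[name], tr, float(theta0[i])))
    for j, lab in enumerate(labels):
        specs.append(
            ParamSpec(f"h_{lab}", prior_map.get(f"h_{lab}", HalfNormal(2.0)), Log(),
                      float(theta0[len(scalar) + j]))
        )
    return specs


# ---------------------------------------------------------------------------
# Derived outputs
# ---------------------------------------------------------------------------


def weighted_aux_sum(
    params: CombinedParams, data: CombinedData, impute: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """C51*activity + C52*HR + C53*HRV on the CGM grid.

    Returns (series, valid mask). With ``impute=True`` missing aux entries
    are filled with Model-2 smoothed estimates before weighting, so the
    returned mask is all-True wherever imputation succeeded.
    """
    aux = data.y[:, :3].copy()
    have = data.mask[:, :3].copy()
    if impute:
        sm_all = _cardio_smoothed_on_grid(params.cardio, data)
        aux = np.where(have, aux, sm_all)
        have = np.ones_like(have)
    w = params.couplings
    series = aux @ w
    valid = have.all(axis=1)
    return series, valid


def _cardio_smoothed_on_grid(cardio: CardioParams, data: CombinedData) -> np.ndarray:
    cd = data.cardio
    m = circadian_means(cardio, cd.times)
    res = kalman_filter(
        build_cardio_system(cardio), cd.times, cd.y, cd.mask, m,
        cardio.sigma_vec() ** 2, np.eye(3),
    )
    sm, _ = kalman_smooth(res)
    full = sm + m
    out = np.zeros((data.times.size, 3))
    for i in range(3):
        vals, got = _aggregate_to_grid(
            cd.times, full[:, i], np.ones(cd.times.size, dtype=bool), data.times
        )
        # outside the cardio recording fall back to the circadian mean
        out[:, i] = np.where(got, vals, np.interp(data.times, cd.times, full[:, i]))
    return out


def cross_correlation(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    max_lag: float,
    valid_x: np.ndarray | None = None,
    valid_y: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pearson correlation of two equally gridded series at integer-step
    lags in [-max_lag, +max_lag] hours.

    Missing pairs are dropped per lag; lags with < 3 overlapping points
    are NaN. Returns (lags_hours, correlations, argmax lag in hours).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = np.ones(x.size, bool) if valid_x is None else np.asarray(valid_x, bool)
    vy = np.ones(y.size, bool) if valid_y is None else np.asarray(valid_y, bool)
    L = int(np.floor(max_lag / dt))
    lags = np.arange(-L, L + 1)
    corr = np.full(lags.size, np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xa, ya = x[: x.size - lag], y[lag:]
            va = vx[: x.size - lag] & vy[lag:]
        else:
            xa, ya = x[-lag:], y[: y.size + lag]
            va = vx[-lag:] & vy[: y.size + lag]
        if np.count_nonzero(va) < 3:
            continue
        xs, ys = xa[va], ya[va]
        sx, sy = np.std(xs), np.std(ys)
        if sx == 0 or sy == 0:
            continue
        corr[i] = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    best = int(np.nanargmax(corr))
    return lags * dt, corr, float(lags[best] * dt)


def single_input_variant(
    data: CombinedData,
    cardio_locked: CardioParams,
    glucose: GlucoseParams,
    input_channel: Channel,
    hmc_config=None,
    seed: int = 0,
    refit_glucose: bool = False,
):
    """Refit with a single aux input into glucose (other couplings at 0).

    Returns (coupling name, PosteriorSamples, ParamModel). By default the
    glucose block stays locked at the supplied parameters so only the one
    coupling is sampled; ``refit_glucose=True`` samples it jointly.
    """
    from wearssm.inference import HMCConfig, hmc_sample, map_estimate

    name = _COUPLING_NAMES[list(AUX_CHANNELS).index(input_channel)]
    model = model3_param_model(
        data,
        cardio_locked,
        glucose_init=glucose,
        active_couplings=(name,),
        glucose_locked=None if refit_glucose else glucose,
    )
    mp = map_estimate(model)
    cfg = hmc_config or HMCConfig(stage1_warmup=100, stage1_draws=100, warmup=200, draws=300)
    samples = hmc_sample(model, init=mp.theta, config=cfg, seed=seed)
    return name, samples, model


def glucose_variance_decomposition(
    params: CombinedParams,
    data: CombinedData,
    draws: Sequence[CombinedParams] | None = None,
    qs=(5, 50, 95),
) -> dict:
    """Explained variance of glucose: meals+circadian vs +aux channels.

    The aux-informed prediction adds the smoothed glucose-state estimate
    conditioned on the observed aux channels (glucose itself masked out).
    Per-draw summaries are returned when ``draws`` is given.
    """
    obs = data.mask[:, 3]
    y = data.y[obs, 3]
    vy = float(np.var(y))

    def _pair(p: CombinedParams) -> tuple[float, float]:
        m = observation_means(p, data)
        base = m[obs, 3]
        mask = data.mask & np.array([True, True, True, False])[None, :]
        res = kalman_filter(
            build_combined_system(p), data.times, data.y, mask, m,
            _sigma4(p), H_COMBINED,
        )
        sm, _ = kalman_smooth(res)
        full = base + sm[obs, 4]
        return (
            1.0 - float(np.var(y - base)) / vy,
            1.0 - float(np.var(y - full)) / vy,
        )

    ev1, ev2 = _pair(params)
    out = {"ev_meals_circadian": ev1, "ev_with_aux": ev2}
    if draws is not None:
        pairs = np.array([_pair(p) for p in draws])
        out["ev_meals_circadian_q"] = {
            f"p{q}": float(np.percentile(pairs[:, 0], q)) for q in qs
        }
        out["ev_with_aux_q"] = {
            f"p{q}": float(np.percentile(pairs[:, 1], q)) for q in qs
        }
    return out
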