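"""Model 1: glucose dynamics with meal impulse responses and a circadian
baseline, plus the derived personalized metrics.

The latent state is 2-D: an unobserved feedback variable and the glucose
level. Meals perturb the feedback variable; the deterministic response on
the glucose channel, normalized to unit peak and scaled by a per-label
height, enters the observation mean together with a 24-h sinusoid.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import scipy.optimize as sopt
from numba import njit

from wearssm._kalman import LOG2PI

from wearssm.datamodel_io import MealEvent, ParticipantRecord
from wearssm.inference import (
    Flat,
    HalfNormal,
    Identity,
    Log,
    LogNormal,
    Normal,
    ParamModel,
    ParamSpec,
)
from wearssm.ssm_core import LTISystem, kalman_filter

OMEGA = 2.0 * math.pi / 24.0  # circadian frequency, fixed
H_GLUCOSE = np.array([[0.0, 1.0]])


@dataclasses.dataclass
class GlucoseParams:
    """All Model-1 parameters for one participant."""

    A11: float
    A12: float
    A21: float
    A22: float
    B22: float
    sigma: float
    A0: float
    A1: float = 0.0
    phi: float = 0.0
    heights: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("A11", "A12", "A21", "A22"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.B22 < 0:
            raise ValueError("B22 must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.A1 < 0:
            raise ValueError("A1 (circadian amplitude) must be nonnegative")
        for lab, h in self.heights.items():
            if h < 0:
                raise ValueError(f"meal height for {lab!r} must be nonnegative")

    @property
    def W(self) -> np.ndarray:
        return np.array([[-self.A11, -self.A12], [self.A21, -self.A22]])

    @property
    def Q(self) -> np.ndarray:
        return np.array([[0.0, 0.0], [0.0, self.B22]])

    def system(self) -> LTISystem:
        return LTISystem(self.W, self.Q)


# ---------------------------------------------------------------------------
# Deterministic response machinery (closed forms for the 2x2 drift)
# ---------------------------------------------------------------------------


def _mu_delta(W: np.ndarray) -> tuple[float, complex]:
    mu = 0.5 * float(np.trace(W))
    delta = np.sqrt(complex(mu * mu - float(np.linalg.det(W))))
    return mu, delta


def impulse_shape(W: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Glucose-channel response [expm(W tau)]_{21} to a unit kick in x1.

    Evaluated with the 2x2 closed form e^{mu tau} sinh(delta tau)/delta,
    computed in the overflow-safe split-exponential form (both exponents
    have negative real part for a stable W).
    """
    mu, delta = _mu_delta(W)
    tau = np.asarray(tau, dtype=float)
    if abs(delta) < 1e-10:
        core = tau * np.exp(mu * tau)
    else:
        core = np.real(
            (np.exp((mu + delta) * tau) - np.exp((mu - delta) * tau)) / (2.0 * delta)
        )
    return float(W[1, 0]) * core


def response_peak(W: np.ndarray) -> tuple[float, float]:
    """(peak time, peak value) of the unit-kick glucose response."""
    if np.trace(W) >= 0 or np.linalg.det(W) <= 0:
        raise ValueError("response peak requires a stable drift matrix")
    mu, delta = _mu_delta(W)
    if abs(delta) < 1e-10:
        t_peak = -1.0 / mu
    else:
        t_peak = float(np.real(np.arctanh(-delta / mu) / delta))
    peak = float(impulse_shape(W, np.array([t_peak]))[0])
    if peak <= 0:
        raise ValueError("degenerate impulse response (A21 must be positive)")
    return t_peak, peak


def _decay_rate(W: np.ndarray) -> float:
    mu, delta = _mu_delta(W)
    return max(1e-3, -(mu + abs(delta.real)))


def meal_response(
    params: GlucoseParams,
    meals: Sequence[MealEvent],
    t: np.ndarray,
    support: float = 72.0,
) -> np.ndarray:
    """Summed meal response r(t) in mmol/L on a time grid.

    Each event contributes the unit-peak-normalized deterministic impulse
    response scaled by its label's height; responses superpose linearly
    and vanish before the event. Contributions are truncated once the
    decay envelope falls below 1e-6 of the peak (capped at ``support`` h).
    """
    t = np.asarray(t, dtype=float)
    r = np.zeros_like(t)
    if not meals:
        return r
    W = params.W
    _, peak = response_peak(W)
    tail = min(support, 27.7 / _decay_rate(W))  # exp(-27.7) ~ 1e-12
    for ev in meals:
        if ev.label not in params.heights:
            raise KeyError(f"no height parameter for meal label {ev.label!r}")
        h = params.heights[ev.label]
        if h == 0.0:
            continue
        lo = int(np.searchsorted(t, ev.time, side="left"))
        hi = int(np.searchsorted(t, ev.time + tail, side="right"))
        if lo >= hi:
            continue
        tau = t[lo:hi] - ev.time
        r[lo:hi] += (h / peak) * impulse_shape(W, tau)
    return r


def circadian_baseline(A0: float, A1: float, phi: float, t: np.ndarray) -> np.ndarray:
    """g(t) = A0 + A1 (1 + cos(omega (t - phi)))/2; peak A0+A1 at clock
    time phi, trough A0 half a period later."""
    t = np.asarray(t, dtype=float)
    return A0 + 0.5 * A1 * (1.0 + np.cos(OMEGA * (t - phi)))


def damping_coefficient(W: np.ndarray) -> float:
    """-det(W - I tr(W)/2) / (tr(W)/2)^2: negative iff eigenvalues are
    complex (underdamped/dipping), positive iff real distinct, 0 at the
    critically damped boundary."""
    W = np.asarray(W, dtype=float)
    mu = 0.5 * float(np.trace(W))
    if mu == 0:
        raise ValueError("damping coefficient undefined for tr(W) = 0")
    shifted = W - mu * np.eye(2)
    return float(-np.linalg.det(shifted) / mu**2)


def half_life(params: GlucoseParams | np.ndarray, max_horizon: float = 72.0) -> float:
    """Time after the response peak for the unit-peak meal response to
    fall to 0.5 mmol/L, refined to 1e-6 h."""
    W = params.W if isinstance(params, GlucoseParams) else np.asarray(params, float)
    t_peak, peak = response_peak(W)

    def f(tau: float) -> float:
        return float(impulse_shape(W, np.array([tau]))[0]) / peak - 0.5

    step = max(t_peak, 0.05)
    lo = t_peak
    hi = lo + step
    while f(hi) > 0:
        lo, hi = hi, hi + step
        if hi - t_peak > max_horizon:
            raise ValueError("response does not reach 0.5 within the horizon")
    root = sopt.brentq(f, lo, hi, xtol=1e-9)
    return float(root - t_peak)


def cosinor_fit(t: np.ndarray, y: np.ndarray, period: float = 24.0) -> tuple[float, float, float]:
    """Least-squares fit of mesor + cosine; returns (mesor, trough-to-peak
    amplitude, peak time in [0, period))."""
    w = 2.0 * math.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = 2.0 * math.hypot(beta[1], beta[2])
    phase = math.atan2(beta[2], beta[1]) / w % period
    return float(beta[0]), float(amp), float(phase)


# ---------------------------------------------------------------------------
# Likelihood / ParamModel construction
# ---------------------------------------------------------------------------


def observation_mean(
    params: GlucoseParams, meals: Sequence[MealEvent], t: np.ndarray
) -> np.ndarray:
    r = meal_response(params, meals, t)
    g = circadian_baseline(params.A0, params.A1, params.phi, t)
    return r + g


def model1_loglik(params: GlucoseParams, record: ParticipantRecord) -> float:
    """Exact Kalman log-likelihood of the (detrended) glucose series."""
    t_obs, y_obs = record.glucose.observed_arrays()
    m = observation_mean(params, record.meals, t_obs)
    res = kalman_filter(
        params.system(),
        t_obs,
        y_obs[:, None],
        np.ones((t_obs.size, 1), dtype=bool),
        m[:, None],
        np.full((t_obs.size, 1), params.sigma**2),
        H_GLUCOSE,
    )
    return res.loglik


# -- fast likelihood path ---------------------------------------------------
# The sampler evaluates the likelihood tens of thousands of times per fit;
# the generic ssm_core route is exact but pays matrix-exponential and
# allocation overhead per call. For Model 1 the 2x2 structure gives closed
# forms for F, the stationary covariance and the meal-response mean (an
# O(T+M) complex-exponential recursion), all verified against the generic
# path in the test suite.


@njit(cache=True)
def _gluc_mean_core(t, meal_t, ev_h, lam1, lam2, scale, mu, degen_scale,
                    degenerate, A0, A1, phi):
    omega = 2.0 * np.pi / 24.0
    T = t.size
    M = meal_t.size
    out = np.empty(T)
    E1 = 0.0j
    E2 = 0.0j
    accA = 0.0  # degenerate (repeated-eigenvalue) accumulators
    accB = 0.0
    j = 0
    tprev = t[0] if T else 0.0
    for k in range(T):
        dt = t[k] - tprev
        if k > 0:
            if degenerate:
                e = np.exp(mu * dt)
                accB = e * (accB + dt * accA)
                accA = e * accA
            else:
                E1 *= np.exp(lam1 * dt)
                E2 *= np.exp(lam2 * dt)
        while j < M and meal_t[j] <= t[k]:
            tau = t[k] - meal_t[j]
            h = ev_h[j]
            if degenerate:
                accA += h * np.exp(mu * tau)
                accB += h * tau * np.exp(mu * tau)
            else:
                E1 += h * np.exp(lam1 * tau)
                E2 += h * np.exp(lam2 * tau)
            j += 1
        r = degen_scale * accB if degenerate else (scale * (E1 - E2)).real
        out[k] = r + A0 + 0.5 * A1 * (1.0 + np.cos(omega * (t[k] - phi)))
        tprev = t[k]
    return out


@njit(cache=True)
def _gluc_kalman(y, m, sig2, Fu, Qu, step_idx, p11_0, p12_0, p22_0):
    # scalar-arithmetic filter for the 2-state single-channel model,
    # H = [0, 1]; transitions indexed per step from the unique-dt tables;
    # the covariance update K S K^T keeps P symmetric exactly
    T = y.size
    x1 = 0.0
    x2 = 0.0
    p11, p12, p22 = p11_0, p12_0, p22_0
    ll = 0.0
    for k in range(T):
        if k > 0:
            u = step_idx[k]
            f11 = Fu[u, 0]
            f12 = Fu[u, 1]
            f21 = Fu[u, 2]
            f22 = Fu[u, 3]
            nx1 = f11 * x1 + f12 * x2
            nx2 = f21 * x1 + f22 * x2
            a11 = f11 * p11 + f12 * p12
            a12 = f11 * p12 + f12 * p22
            a21 = f21 * p11 + f22 * p12
            a22 = f21 * p12 + f22 * p22
            p11 = a11 * f11 + a12 * f12 + Qu[u, 0]
            p12 = a11 * f21 + a12 * f22 + Qu[u, 1]
            p22 = a21 * f21 + a22 * f22 + Qu[u, 2]
            x1, x2 = nx1, nx2
        S = p22 + sig2
        if not S > 0.0:
            return np.nan
        v = y[k] - m[k] - x2
        ll += -0.5 * (LOG2PI + np.log(S) + v * v / S)
        k1 = p12 / S
        k2 = p22 / S
        x1 += k1 * v
        x2 += k2 * v
        p11 -= k1 * k1 * S
        p12 -= k1 * k2 * S
        p22 -= k2 * k2 * S
    return ll


def _stationary_2x2(A11: float, A12: float, A21: float, A22: float, B22: float):
    # W P + P W^T + Q = 0 written out for the three unique entries
    M = np.array(
        [
            [-2.0 * A11, -2.0 * A12, 0.0],
            [A21, -(A11 + A22), -A12],
            [0.0, 2.0 * A21, -2.0 * A22],
        ]
    )
    p11, p12, p22 = np.linalg.solve(M, np.array([0.0, 0.0, -B22]))
    return p11, p12, p22


def _expm_2x2(W: np.ndarray, dt: float) -> np.ndarray:
    mu, delta = _mu_delta(W)
    x = delta * dt
    if abs(x) < 1e-8:
        e = math.exp(mu * dt)
        ech, eshd = e * (1.0 + 0.5 * (x * x).real), e * dt * (1.0 + (x * x).real / 6.0)
    else:
        E1, E2 = np.exp((mu + delta) * dt), np.exp((mu - delta) * dt)
        ech = (0.5 * (E1 + E2)).real
        eshd = ((E1 - E2) / (2.0 * delta)).real
    return ech * np.eye(2) + eshd * np.real(W - mu * np.eye(2))


def _fast_model1_loglik(
    theta: np.ndarray,
    labels: list[str],
    include_circadian: bool,
    t_obs: np.ndarray,
    y_obs: np.ndarray,
    meal_t: np.ndarray,
    meal_label_idx: np.ndarray,
    uniq_dts: np.ndarray,
    step_idx: np.ndarray,
) -> float:
    A11, A12, A21, A22, B22, sigma, A0 = theta[:7]
    n_scalar = 7
    if include_circadian:
        A1, phi = theta[7], theta[8]
        n_scalar = 9
    else:
        A1, phi = 0.0, 0.0
    heights = theta[n_scalar:]
    if not np.all(np.isfinite(theta)) or abs(A11) > 1e8 or abs(A22) > 1e8:
        return -np.inf
    mu = -0.5 * (A11 + A22)
    det = A11 * A22 + A12 * A21
    if not (np.isfinite(mu) and np.isfinite(det)):
        return -np.inf
    delta = np.sqrt(complex(mu * mu - det))
    degenerate = abs(delta) < 1e-12
    with np.errstate(all="ignore"):
        if degenerate:
            t_peak = -1.0 / mu
            peak = A21 * t_peak * math.exp(mu * t_peak)
        else:
            t_peak = float(np.real(np.arctanh(-delta / mu) / delta))
            peak = A21 * float(
                np.real(
                    (np.exp((mu + delta) * t_peak) - np.exp((mu - delta) * t_peak))
                    / (2.0 * delta)
                )
            )
    if not peak > 0 or not np.isfinite(t_peak):
        return -np.inf
    scale = A21 / (2.0 * delta * peak) if not degenerate else 0.0j
    ev_h = heights[meal_label_idx] if meal_t.size else np.empty(0)
    m = _gluc_mean_core(
        t_obs, meal_t, ev_h, mu + delta, mu - delta, scale, mu,
        A21 / peak, degenerate, A0, A1, phi,
    )
    p11, p12, p22 = _stationary_2x2(A11, A12, A21, A22, B22)
    U = uniq_dts.size
    Fu = np.empty((U, 4))
    Qu = np.empty((U, 3))
    for i in range(U):
        dt = float(uniq_dts[i])
        x = delta * dt
        # expm(W dt) = e^{mu dt}(cosh(d dt) I + sinh(d dt)/d (W - mu I)),
        # evaluated via split exponentials (negative real parts, no overflow)
        if abs(x) < 1e-8:
            e = math.exp(mu * dt)
            ech = e * (1.0 + 0.5 * (x * x).real)
            eshd = e * dt * (1.0 + (x * x).real / 6.0)
        else:
            E1 = np.exp((mu + delta) * dt)
            E2 = np.exp((mu - delta) * dt)
            ech = (0.5 * (E1 + E2)).real
            eshd = ((E1 - E2) / (2.0 * delta)).real
        f11 = ech + eshd * (-A11 - mu)
        f12 = eshd * -A12
        f21 = eshd * A21
        f22 = ech + eshd * (-A22 - mu)
        Fu[i] = f11, f12, f21, f22
        # Sigma(dt) = Pinf - F Pinf F^T
        a11 = f11 * p11 + f12 * p12
        a12 = f11 * p12 + f12 * p22
        a21 = f21 * p11 + f22 * p12
        a22 = f21 * p12 + f22 * p22
        Qu[i, 0] = p11 - (a11 * f11 + a12 * f12)
        Qu[i, 1] = p12 - (a11 * f21 + a12 * f22)
        Qu[i, 2] = p22 - (a21 * f21 + a22 * f22)
    ll = _gluc_kalman(y_obs, m, sigma * sigma, Fu, Qu, step_idx, p11, p12, p22)
    return float(ll)


_SCALAR_ORDER = ("A11", "A12", "A21", "A22", "B22", "sigma", "A0", "A1", "phi")


def _theta_to_params(
    theta: np.ndarray, labels: list[str], include_circadian: bool
) -> GlucoseParams:
    n_scalar = 9 if include_circadian else 7
    vals = dict(zip(_SCALAR_ORDER[:7], theta[:7]))
    if include_circadian:
        vals["A1"], vals["phi"] = theta[7], theta[8] % 24.0
    else:
        vals["A1"], vals["phi"] = 0.0, 0.0
    heights = dict(zip(labels, theta[n_scalar:]))
    return GlucoseParams(heights=heights, **vals)


def params_to_theta(params: GlucoseParams, labels: list[str], include_circadian: bool = True) -> np.ndarray:
    base = [params.A11, params.A12, params.A21, params.A22, params.B22, params.sigma, params.A0]
    if include_circadian:
        base += [params.A1, params.phi]
    return np.array(base + [params.heights[lab] for lab in labels], dtype=float)


def default_init(record: ParticipantRecord, include_circadian: bool = True) -> GlucoseParams:
    """Data-informed starting point for MAP/HMC."""
    t, y = record.glucose.observed_arrays()
    mesor, amp, phase = cosinor_fit(t, y)
    labels = sorted({m.label for m in record.meals})
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.25
    b22 = max(1e-3, float(np.var(np.diff(y)) / (2.0 * dt)))
    a1 = min(max(amp, 0.05), 3.0) if include_circadian else 0.0
    return GlucoseParams(
        A11=1.0,
        A12=1.0,
        A21=1.0,
        A22=1.0,
        B22=b22,
        sigma=0.3,
        A0=float(np.percentile(y, 20)),
        A1=a1,
        phi=phase if include_circadian else 0.0,
        heights={lab: 1.0 for lab in labels},
    )


def model1_param_model(
    record: ParticipantRecord,
    include_circadian: bool = True,
    priors: dict[str, object] | None = None,
    init: GlucoseParams | None = None,
) -> ParamModel:
    """Bayesian Model 1 over the record's glucose series and meal log.

    Weakly informative defaults: log-normal (median 0.5/h, log-sd 1) on
    rates, half-normal(2) on heights/amplitude/SDs, flat circular phase,
    Normal(5, 3) baseline; all overridable through ``priors``.
    """
    labels = sorted({m.label for m in record.meals})
    init = init or default_init(record, include_circadian)
    prior_map = {
        "A11": LogNormal(0.5, 1.0),
        "A12": LogNormal(0.5, 1.0),
        "A21": LogNormal(0.5, 1.0),
        "A22": LogNormal(0.5, 1.0),
        "B22": HalfNormal(2.0),
        "sigma": HalfNormal(2.0),
        "A0": Normal(5.0, 3.0),
        "A1": HalfNormal(2.0),
        "phi": Flat(),
    }
    if priors:
        prior_map.update(priors)

    specs = []
    scalar = _SCALAR_ORDER[:9] if include_circadian else _SCALAR_ORDER[:7]
    init_theta = params_to_theta(init, labels, include_circadian)
    for i, name in enumerate(scalar):
        tr = Log() if name not in ("A0", "phi") else Identity()
        specs.append(ParamSpec(name, prior_map[name], tr, float(init_theta[i])))
    for j, lab in enumerate(labels):
        specs.append(
            ParamSpec(
                f"h_{lab}",
                prior_map.get(f"h_{lab}", HalfNormal(2.0)),
                Log(),
                float(init_theta[len(scalar) + j]),
            )
        )

    t_obs, y_obs = record.glucose.observed_arrays()
    label_pos = {lab: i for i, lab in enumerate(labels)}
    meal_t = np.array([m.time for m in record.meals], dtype=float)
    meal_idx = np.array([label_pos[m.label] for m in record.meals], dtype=np.int64)
    dts_rounded = np.round(np.diff(t_obs), 12)
    uniq_dts, inv = np.unique(dts_rounded, return_inverse=True)
    step_idx = np.concatenate([[0], inv]).astype(np.int64)
    y_obs = np.ascontiguousarray(y_obs)

    def loglik(theta: np.ndarray) -> float:
        return _fast_model1_loglik(
            theta, labels, include_circadian, t_obs, y_obs,
            meal_t, meal_idx, uniq_dts, step_idx,
        )

    model = ParamModel(specs, loglik)
    model.labels = labels  # type: ignore[attr-defined]
    model.include_circadian = include_circadian  # type: ignore[attr-defined]
    model.to_params = lambda theta: _theta_to_params(theta, labels, include_circadian)  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GlucoseMetrics:
    half_life: float
    damping: float
    mean_meal_height: float
    circadian_amplitude: float
    circadian_peak_time: float
    ev_meals: float | None = None
    ev_meals_circadian: float | None = None


def mean_meal_height(params: GlucoseParams, meals: Sequence[MealEvent]) -> float:
    """Mean inferred height over all consumed meal events (each occurrence
    counted)."""
    if not meals:
        return 0.0
    return float(np.mean([params.heights[m.label] for m in meals]))


def glucose_metrics(
    params: GlucoseParams,
    meals: Sequence[MealEvent],
    record: ParticipantRecord | None = None,
) -> GlucoseMetrics:
    ev1 = ev2 = None
    if record is not None:
        t, y = record.glucose.observed_arrays()
        r = meal_response(params, meals, t)
        g = circadian_baseline(params.A0, params.A1, params.phi, t)
        vy = float(np.var(y))
        ev1 = 1.0 - float(np.var(y - r)) / vy
        ev2 = 1.0 - float(np.var(y - r - g)) / vy
    return GlucoseMetrics(
        half_life=half_life(params),
        damping=damping_coefficient(params.W),
        mean_meal_height=mean_meal_height(params, meals),
        circadian_amplitude=params.A1,
        circadian_peak_time=params.phi % 24.0,
        ev_meals=ev1,
        ev_meals_circadian=ev2,
    )
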