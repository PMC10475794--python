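"""Continuous-time linear SDEs as discrete Gaussian state-space models.

Provides exact discretization (matrix exponential + matrix-fraction
decomposition for the process-noise integral), Kalman filtering and
fixed-interval smoothing with exact Gaussian log-likelihoods under
arbitrary per-step missingness, and reproducible path simulation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.linalg as sla

from wearssm._kalman import LOG2PI, kalman_core


class NumericalError(RuntimeError):
    """Filtering/discretization produced a non-finite or non-PSD quantity."""


@dataclasses.dataclass(frozen=True)
class LTISystem:
    """dx = W x dt + dbeta with Brownian covariance Q."""

    W: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "Q", Q)
        if W.shape[0] != W.shape[1] or W.shape != Q.shape:
            raise ValueError("W and Q must be square and the same shape")
        if not np.allclose(Q, Q.T, atol=1e-12):
            raise ValueError("Q must be symmetric")
        if np.any(np.linalg.eigvalsh(0.5 * (Q + Q.T)) < -1e-10):
            raise ValueError("Q must be positive semidefinite")

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.W).real < 0))


@dataclasses.dataclass(frozen=True)
class DiscreteTransition:
    """x_k = F x_{k-1} + N(0, Sigma) over a step of length dt."""

    F: np.ndarray
    Sigma: np.ndarray
    dt: float


@dataclasses.dataclass
class ObservationSpec:
    """Per-step observation y = H x + N(m, R); H may have zero rows."""

    H: np.ndarray
    m: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if self.H.shape[0] != self.m.shape[0] or self.R.shape != (
            self.H.shape[0],
            self.H.shape[0],
        ):
            raise ValueError("H rows, m and R dimensions must agree")


@dataclasses.dataclass
class FilterResult:
    times: np.ndarray
    loglik: float
    step_loglik: np.ndarray
    pred_mean: np.ndarray
    pred_cov: np.ndarray
    filt_mean: np.ndarray
    filt_cov: np.ndarray
    Fs: np.ndarray  # per-step transitions, index 0 unused

    def __len__(self) -> int:
        return int(self.times.size)


def discretize(sys: LTISystem, dt: float) -> DiscreteTransition:
    """Exact (F, Sigma) for a step of length dt.

    F = expm(W dt); Sigma = int_0^dt expm(W s) Q expm(W^T s) ds via the
    matrix-fraction decomposition on the stacked 2d x 2d block system.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    d = sys.d
    if dt == 0:
        return DiscreteTransition(np.eye(d), np.zeros((d, d)), 0.0)
    M = np.zeros((2 * d, 2 * d))
    M[:d, :d] = sys.W
    M[:d, d:] = sys.Q
    M[d:, d:] = -sys.W.T
    E = sla.expm(M * dt)
    F = E[:d, :d]
    Sigma = E[:d, d:] @ F.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(Sigma))):
        raise NumericalError("nonfinite entries in discretized transition")
    return DiscreteTransition(F, Sigma, float(dt))


def stationary_covariance(sys: LTISystem) -> np.ndarray:
    """Solve W S + S W^T + Q = 0 (requires a stable system)."""
    if not sys.stable:
        raise ValueError("stationary covariance requires a stable system")
    S = sla.solve_continuous_lyapunov(sys.W, -sys.Q)
    return 0.5 * (S + S.T)


def transitions_for_times(sys: LTISystem, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (Fs, Sigmas) arrays; index 0 holds identity / zero.

    Unique step lengths are discretized once and reused (a nominal
    15-minute grid with gaps yields only a handful of distinct dts).
    """
    times = np.asarray(times, dtype=float)
    T = times.size
    d = sys.d
    Fs = np.empty((T, d, d))
    Qs = np.empty((T, d, d))
    Fs[0] = np.eye(d)
    Qs[0] = 0.0
    if T > 1:
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        rounded = np.round(dts, 12)
        for dt in np.unique(rounded):
            tr = discretize(sys, float(dt))
            idx = np.where(rounded == dt)[0] + 1
            Fs[idx] = tr.F
            Qs[idx] = tr.Sigma
    return Fs, Qs


def _initial_state(
    sys: LTISystem, x0: np.ndarray | None, P0: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    # default: stationary distribution with mean 0 in deviation coordinates
    if P0 is None:
        P0 = stationary_covariance(sys)
    if x0 is None:
        x0 = np.zeros(sys.d)
    return np.asarray(x0, dtype=float), np.asarray(P0, dtype=float)


def kalman_filter(
    sys: LTISystem,
    times: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    mean: np.ndarray,
    obs_var: np.ndarray,
    H: np.ndarray,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
) -> FilterResult:
    """Fast masked filter: fixed H (p x d), diagonal R, per-step missingness.

    ``y``, ``mask``, ``mean`` and ``obs_var`` are (T, p); masked-out
    entries perform prediction only and contribute 0 to the likelihood.
    """
    times = np.asarray(times, dtype=float)
    y = np.ascontiguousarray(np.atleast_2d(np.asarray(y, dtype=float).T).T)
    T, p = y.shape
    mask8 = np.ascontiguousarray(np.asarray(mask, dtype=bool).reshape(T, p).astype(np.uint8))
    mean = np.ascontiguousarray(np.asarray(mean, dtype=float).reshape(T, p))
    obs_var = np.asarray(obs_var, dtype=float)
    if obs_var.ndim <= 1:
        obs_var = np.broadcast_to(np.atleast_1d(obs_var), (T, p))
    obs_var = np.ascontiguousarray(obs_var.reshape(T, p))
    H = np.ascontiguousarray(np.asarray(H, dtype=float).reshape(p, sys.d))
    x0, P0 = _initial_state(sys, x0, P0)
    Fs, Qs = transitions_for_times(sys, times)
    yz = np.where(mask8.astype(bool), y, 0.0)  # keep NaNs out of the kernel
    ok, ll, step_ll, pm, pP, fm, fP = kalman_core(
        yz, mask8, mean, obs_var, H, Fs, Qs, x0, P0
    )
    if not ok or not np.isfinite(ll):
        raise NumericalError(
            "non-PSD innovation covariance during filtering; check Q/R "
            "conditioning and parameter scales"
        )
    return FilterResult(times, float(ll), step_ll, pm, pP, fm, fP, Fs)


def kalman_loglik(
    sys: LTISystem,
    obs: Sequence[tuple[float, ObservationSpec, np.ndarray]],
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
) -> tuple[float, FilterResult]:
    """General filter over (time, ObservationSpec, data) triples.

    Reference implementation supporting arbitrary per-step H/m/R (dense R
    allowed); used for cross-checks and small problems. Returns the total
    log-likelihood and the :class:`FilterResult`.
    """
    times = np.array([t for t, _, _ in obs], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    x, P = _initial_state(sys, x0, P0)
    d = sys.d
    T = len(obs)
    Fs, Qs = transitions_for_times(sys, times)
    step_ll = np.zeros(T)
    pm = np.zeros((T, d))
    pP = np.zeros((T, d, d))
    fm = np.zeros((T, d))
    fP = np.zeros((T, d, d))
    ll = 0.0
    for k, (_, spec, data) in enumerate(obs):
        if k > 0:
            x = Fs[k] @ x
            P = Fs[k] @ P @ Fs[k].T + Qs[k]
            P = 0.5 * (P + P.T)
        pm[k], pP[k] = x, P
        Hk, mk, Rk = spec.H, spec.m, spec.R
        if Hk.shape[0] > 0:
            v = np.atleast_1d(np.asarray(data, dtype=float)) - mk - Hk @ x
            S = Hk @ P @ Hk.T + Rk
            S = 0.5 * (S + S.T)
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"non-PSD innovation covariance at step {k}: "
                    f"eigvals={np.linalg.eigvalsh(S)}"
                ) from exc
            alpha = sla.cho_solve((L, True), v)
            step_ll[k] = -0.5 * (
                v.size * LOG2PI + v @ alpha
            ) - np.sum(np.log(np.diag(L)))
            ll += step_ll[k]
            K = sla.cho_solve((L, True), Hk @ P).T
            x = x + K @ v
            IKH = np.eye(d) - K @ Hk
            P = IKH @ P @ IKH.T + K @ Rk @ K.T
            P = 0.5 * (P + P.T)
        fm[k], fP[k] = x, P
    result = FilterResult(times, float(ll), step_ll, pm, pP, fm, fP, Fs)
    return float(ll), result


def kalman_smooth(result: FilterResult) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-interval (RTS) smoothing from a completed forward pass."""
    T = len(result)
    d = result.filt_mean.shape[1]
    sm = result.filt_mean.copy()
    sP = result.filt_cov.copy()
    for k in range(T - 2, -1, -1):
        F = result.Fs[k + 1]
        Ppred = result.pred_cov[k + 1]
        # guard against (near-)singular predictive covariances
        G = result.filt_cov[k] @ F.T @ sla.pinvh(Ppred)
        sm[k] = result.filt_mean[k] + G @ (sm[k + 1] - result.pred_mean[k + 1])
        sPk = result.filt_cov[k] + G @ (sP[k + 1] - Ppred) @ G.T
        sP[k] = 0.5 * (sPk + sPk.T)
    return sm, sP


def _sqrt_psd(S: np.ndarray) -> np.ndarray:
    # robust matrix square root for PSD matrices (eigh, clipped)
    vals, vecs = np.linalg.eigh(0.5 * (S + S.T))
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals))


def simulate_path(
    sys: LTISystem,
    times: np.ndarray,
    H: np.ndarray,
    mean: np.ndarray | None = None,
    obs_sd: np.ndarray | float = 0.0,
    seed: int | np.random.Generator = 0,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
    state_input: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a state path and noisy observations; reproducible given seed.

    ``x0`` fixes the initial state; otherwise it is drawn from N(0, P0)
    (P0 defaulting to the stationary covariance). ``state_input`` is an
    optional (T, d) deterministic additive input applied after each
    transition (used for exercise bouts in the synthetic generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    T = times.size
    d = sys.d
    H = np.atleast_2d(np.asarray(H, dtype=float))
    p = H.shape[0]
    Fs, Qs = transitions_for_times(sys, times)
    if x0 is None:
        P0 = stationary_covariance(sys) if P0 is None else np.asarray(P0, float)
        x = _sqrt_psd(P0) @ rng.standard_normal(d)
    else:
        x = np.asarray(x0, dtype=float).copy()
    states = np.zeros((T, d))
    states[0] = x
    sqrts: dict[int, np.ndarray] = {}
    for k in range(1, T):
        key = k
        # cache noise square roots by unique transition (compare by id of F)
        Fk = Fs[k]
        x = Fk @ x
        Qk = Qs[k]
        if Qk.any():
            h = hash(Qk.tobytes())
            if h not in sqrts:
                sqrts[h] = _sqrt_psd(Qk)
            x = x + sqrts[h] @ rng.standard_normal(d)
        if state_input is not None:
            x = x + state_input[k]
        states[key] = x
    obs = states @ H.T
    if mean is not None:
        obs = obs + np.asarray(mean, dtype=float).reshape(T, p)
    obs_sd = np.broadcast_to(np.asarray(obs_sd, dtype=float), (p,))
    if np.any(obs_sd > 0):
        obs = obs + rng.standard_normal((T, p)) * obs_sd
    return states, obs
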