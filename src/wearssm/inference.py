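"""Priors, MAP optimization, two-stage HMC, BIC comparison and
posterior summaries.

Sampling operates on an unconstrained scale (log for positive rates and
SDs, atanh for correlations); the posterior density includes the Jacobian
of the transform. The HMC protocol is two-stage: a single adaptive chain
tunes a global step size to a 0.75 target acceptance, per-parameter step
scales are then set to the SDs of that initial posterior sample, and the
final chains re-adapt the global step size during the first 80% of their
burn-in only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Callable, Sequence

import numpy as np
import scipy.optimize as sopt

BIC_CUTOFF = 2.0 * math.log(10.0)

# ---------------------------------------------------------------------------
# Transforms (unconstrained u -> constrained theta)
# ---------------------------------------------------------------------------


class Identity:
    def forward(self, u: float) -> float:
        return u

    def inverse(self, theta: float) -> float:
        return theta

    def log_jac(self, u: float) -> float:
        return 0.0


class Log:
    """theta = exp(u) for positive parameters."""

    def forward(self, u: float) -> float:
        return math.exp(u) if u < 709.0 else math.inf

    def inverse(self, theta: float) -> float:
        if theta <= 0:
            raise ValueError("log transform requires a positive value")
        return math.log(theta)

    def log_jac(self, u: float) -> float:
        return u


class Tanh:
    """theta = tanh(u) for correlation-type parameters in (-1, 1)."""

    def forward(self, u: float) -> float:
        return math.tanh(u)

    def inverse(self, theta: float) -> float:
        if not -1 < theta < 1:
            raise ValueError("tanh transform requires a value in (-1, 1)")
        return math.atanh(theta)

    def log_jac(self, u: float) -> float:
        return math.log1p(-math.tanh(u) ** 2)


# ---------------------------------------------------------------------------
# Priors (densities on the constrained scale)
# ---------------------------------------------------------------------------


class Normal:
    def __init__(self, mu: float, sd: float):
        self.mu, self.sd = mu, sd

    def logpdf(self, x: float) -> float:
        z = (x - self.mu) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * math.log(2 * math.pi)


class LogNormal:
    """Parameterized by the median and the SD on the log scale."""

    def __init__(self, median: float, log_sd: float):
        self.mu, self.sd = math.log(median), log_sd

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (math.log(x) - self.mu) / self.sd
        return -0.5 * z * z - math.log(x * self.sd) - 0.5 * math.log(2 * math.pi)


class HalfNormal:
    def __init__(self, sd: float):
        self.sd = sd

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -np.inf
        z = x / self.sd
        return -0.5 * z * z + math.log(2.0) - math.log(self.sd) - 0.5 * math.log(2 * math.pi)


class Flat:
    """Improper constant prior (used for circular phases, reported mod 24)."""

    def logpdf(self, x: float) -> float:
        return 0.0


@dataclasses.dataclass
class ParamSpec:
    name: str
    prior: object
    transform: object = dataclasses.field(default_factory=Identity)
    init: float = 0.0


class ParamModel:
    """A parameter vector with priors/transforms plus a likelihood callable.

    ``loglik_fn`` receives the constrained parameter vector (same order as
    ``specs``). The posterior is evaluated on the unconstrained scale with
    the transform Jacobian included.
    """

    def __init__(self, specs: Sequence[ParamSpec], loglik_fn: Callable[[np.ndarray], float]):
        self.specs = list(specs)
        self.loglik_fn = loglik_fn
        self.names = [s.name for s in self.specs]

    @property
    def k(self) -> int:
        return len(self.specs)

    def init_theta(self) -> np.ndarray:
        return np.array([s.init for s in self.specs], dtype=float)

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        return np.array(
            [s.transform.inverse(t) for s, t in zip(self.specs, theta)], dtype=float
        )

    def to_constrained(self, u: np.ndarray) -> np.ndarray:
        return np.array(
            [s.transform.forward(ui) for s, ui in zip(self.specs, u)], dtype=float
        )

    def log_prior(self, theta: np.ndarray) -> float:
        return float(sum(s.prior.logpdf(t) for s, t in zip(self.specs, theta)))

    def log_posterior_u(self, u: np.ndarray) -> float:
        if not np.all(np.isfinite(u)):
            return -np.inf
        theta = self.to_constrained(u)
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        lp += float(sum(s.transform.log_jac(ui) for s, ui in zip(self.specs, u)))
        try:
            ll = self.loglik_fn(theta)
        except (FloatingPointError, np.linalg.LinAlgError, RuntimeError):
            return -np.inf
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, map(float, theta)))


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MapResult:
    theta: np.ndarray
    u: np.ndarray
    log_posterior: float
    converged: bool
    grad_norm: float
    n_evals: int


def map_estimate(
    model: ParamModel,
    init: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-5,
) -> MapResult:
    """Maximize log prior + log likelihood with BFGS (finite-diff gradients).

    ``init`` is on the constrained scale; defaults to the specs' inits.
    Non-convergence returns the best point found with ``converged=False``.
    """
    theta0 = model.init_theta() if init is None else np.asarray(init, dtype=float)
    u0 = model.to_unconstrained(theta0)

    def neg(u: np.ndarray) -> float:
        v = model.log_posterior_u(u)
        return 1e12 if not np.isfinite(v) else -v

    res = sopt.minimize(
        neg, u0, method="BFGS", options={"maxiter": max_iter, "gtol": gtol}
    )
    u = np.asarray(res.x, dtype=float)
    return MapResult(
        theta=model.to_constrained(u),
        u=u,
        log_posterior=-float(res.fun),
        converged=bool(res.success),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        n_evals=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class HMCConfig:
    """Counts follow the reference protocol but default to reduced values
    suitable for tests; set ``reference()`` for the full protocol."""

    n_leapfrog: int = 5
    target_accept: float = 0.75
    stage1_warmup: int = 300
    stage1_draws: int = 300
    n_chains: int = 1
    warmup: int = 600
    draws: int = 1000
    adapt_fraction: float = 0.8
    init_step: float = 0.1
    fd_eps: float = 1e-5
    max_energy_change: float = 1000.0

    @classmethod
    def reference(cls) -> "HMCConfig":
        return cls(
            stage1_warmup=10_000,
            stage1_draws=10_000,
            n_chains=4,
            warmup=10_000,
            draws=10_000,
        )


@dataclasses.dataclass
class PosteriorSamples:
    names: list[str]
    draws: np.ndarray  # (chains, n, p) constrained scale
    draws_u: np.ndarray  # (chains, n, p) unconstrained scale
    accept_rate: np.ndarray  # per chain
    step_size: float
    scales: np.ndarray
    divergences: int

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def percentiles(self, qs=(5, 25, 50, 75, 95)) -> dict[str, list[float]]:
        flat = self.flat()
        return {
            name: [float(np.percentile(flat[:, i], q)) for q in qs]
            for i, name in enumerate(self.names)
        }

    def to_frame(self):
        import pandas as pd

        C, n, p = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(C), n))
        df.insert(1, "iteration", np.tile(np.arange(n), C))
        return df


def _fd_gradient(
    f: Callable[[np.ndarray], float], u: np.ndarray, f0: float, eps: float
) -> np.ndarray:
    g = np.empty_like(u)
    for i in range(u.size):
        h = eps * (1.0 + abs(u[i]))
        up = u.copy()
        up[i] += h
        fp = f(up)
        if not np.isfinite(fp):
            up[i] = u[i] - h
            fp = f(up)
            g[i] = (f0 - fp) / h if np.isfinite(fp) else 0.0
        else:
            g[i] = (fp - f0) / h
    return g


def _run_chain(
    logpost: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray] | None,
    u0: np.ndarray,
    scales: np.ndarray,
    step: float,
    n_iter: int,
    n_keep: int,
    adapt_until: int,
    cfg: HMCConfig,
    rng: np.random.Generator,
):
    """One HMC chain; returns (kept draws, accept rate, final step, ndiv)."""

    def grad_fn(u: np.ndarray, f0: float) -> np.ndarray:
        if grad is not None:
            return grad(u)
        return _fd_gradient(logpost, u, f0, cfg.fd_eps)

    u = u0.copy()
    lp = logpost(u)
    g = grad_fn(u, lp)
    kept = np.empty((n_keep, u.size))
    n_acc = 0.0
    n_div = 0
    log_step = math.log(step)
    for it in range(n_iter):
        p = rng.standard_normal(u.size)
        H0 = -lp + 0.5 * p @ p
        eps_vec = math.exp(log_step) * scales
        un, lpn, gn = u.copy(), lp, g.copy()
        pn = p + 0.5 * eps_vec * gn  # momentum in scaled coordinates
        diverged = False
        for leap in range(cfg.n_leapfrog):
            un = un + eps_vec * pn
            lpn = logpost(un)
            if not np.isfinite(lpn):
                diverged = True
                break
            gn = grad_fn(un, lpn)
            pn = pn + (eps_vec if leap < cfg.n_leapfrog - 1 else 0.5 * eps_vec) * gn
        if diverged:
            alpha = 0.0
            n_div += 1
        else:
            H1 = -lpn + 0.5 * pn @ pn
            dH = H0 - H1
            if not np.isfinite(dH) or -dH > cfg.max_energy_change:
                alpha = 0.0
                n_div += 1
            else:
                alpha = min(1.0, math.exp(min(0.0, dH)))
        if rng.random() < alpha:
            u, lp, g = un, lpn, gn
        n_acc += alpha
        if it < adapt_until:
            gain = min(0.15, 2.0 / math.sqrt(it + 1.0))
            log_step += gain * (alpha - cfg.target_accept)
        if it >= n_iter - n_keep:
            kept[it - (n_iter - n_keep)] = u
    return kept, n_acc / max(n_iter, 1), math.exp(log_step), n_div


def hmc_sample(
    model: ParamModel,
    init: np.ndarray | None = None,
    config: HMCConfig | None = None,
    seed: int = 0,
    grad: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PosteriorSamples:
    """Two-stage HMC with 5 leapfrog steps per proposal.

    Stage 1 runs a single chain with global step-size adaptation toward
    the target acceptance; the SDs of its draws set per-parameter step
    scales. Stage 2 runs ``n_chains`` chains with global adaptation during
    the first ``adapt_fraction`` of burn-in only.
    """
    cfg = config or HMCConfig()
    logpost = model.log_posterior_u
    if init is None:
        u0 = model.to_unconstrained(model.init_theta())
    else:
        u0 = model.to_unconstrained(np.asarray(init, dtype=float))
    p = u0.size

    rng = np.random.default_rng([seed, 0xA5])
    stage1, acc1, step1, _ = _run_chain(
        logpost,
        grad,
        u0,
        np.ones(p),
        cfg.init_step,
        cfg.stage1_warmup + cfg.stage1_draws,
        cfg.stage1_draws,
        cfg.stage1_warmup,
        cfg,
        rng,
    )
    scales = np.std(stage1, axis=0)
    scales = np.where(scales > 1e-4, scales, 1e-4)

    chains = np.empty((cfg.n_chains, cfg.draws, p))
    chains_u = np.empty_like(chains)
    acc = np.empty(cfg.n_chains)
    ndiv = 0
    step_out = step1
    start = stage1[-1]
    adapt_until = int(cfg.adapt_fraction * cfg.warmup)
    for c in range(cfg.n_chains):
        crng = np.random.default_rng([seed, c + 1])
        kept, acc[c], step_out, dv = _run_chain(
            logpost,
            grad,
            start,
            scales,
            max(step1, 1e-8),
            cfg.warmup + cfg.draws,
            cfg.draws,
            adapt_until,
            cfg,
            crng,
        )
        ndiv += dv
        chains_u[c] = kept
        for i in range(cfg.draws):
            chains[c, i] = model.to_constrained(kept[i])
    return PosteriorSamples(
        names=list(model.names),
        draws=chains,
        draws_u=chains_u,
        accept_rate=acc,
        step_size=float(step_out),
        scales=scales,
        divergences=int(ndiv),
    )


# ---------------------------------------------------------------------------
# Model comparison and summaries
# ---------------------------------------------------------------------------


def bic(loglik: float, k: int, n: int) -> float:
    """k ln(n) - 2 loglik (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) - 2.0 * loglik


def compare_bic(bic_full: float, bic_reduced: float, cutoff: float = BIC_CUTOFF) -> str:
    """Verdict {'full','reduced','inconclusive'}; |delta| equal to the
    cutoff counts as decisive (documented boundary convention)."""
    delta = bic_reduced - bic_full
    if abs(delta) >= cutoff:
        return "full" if delta > 0 else "reduced"
    return "inconclusive"


def explained_variance(
    y: np.ndarray, ytilde: np.ndarray, qs=(5, 50, 95)
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-draw 1 - Var(y - ytilde)/Var(y); ``ytilde`` is (n,) or (draws, n).

    Returns the per-draw values and a percentile summary. EV can be
    negative for predictions worse than the mean.
    """
    y = np.asarray(y, dtype=float)
    yt = np.atleast_2d(np.asarray(ytilde, dtype=float))
    if y.size < 3:
        raise ValueError("need at least 3 paired points")
    vy = float(np.var(y))
    if vy == 0:
        raise ValueError("Var(y) is zero; explained variance undefined")
    ev = 1.0 - np.var(y[None, :] - yt, axis=1) / vy
    summary = {f"p{q}": float(np.percentile(ev, q)) for q in qs}
    return ev, summary


def rhat(draws: np.ndarray | PosteriorSamples) -> np.ndarray:
    """Split-chain potential scale reduction factor per parameter.

    ``draws`` is (chains, n, p) (or a :class:`PosteriorSamples`); each
    chain is split in half before computing the classic between/within
    variance ratio.
    """
    if isinstance(draws, PosteriorSamples):
        draws = draws.draws
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        raise ValueError("need >= 2 chains for R-hat")
    C, n, p = draws.shape
    if C < 2 and n < 4:
        raise ValueError("need >= 2 chains for R-hat")
    half = n // 2
    split = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, nn = split.shape[0], split.shape[1]
    means = split.mean(axis=1)  # (m, p)
    variances = split.var(axis=1, ddof=1)  # (m, p)
    W = variances.mean(axis=0)
    B = nn * means.var(axis=0, ddof=1)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    return out


@dataclasses.dataclass
class FitReport:
    model_name: str
    map_params: dict[str, float]
    posterior_mean: dict[str, float]
    percentiles: dict[str, list[float]]
    rhat: dict[str, float]
    loglik_at_map: float
    bic: float
    n_obs: int
    k: int
    accept_rate: list[float]
    divergences: int
    derived: dict = dataclasses.field(default_factory=dict)
    explained_variance: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "FitReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def build_report(
    model: ParamModel,
    model_name: str,
    map_result: MapResult,
    samples: PosteriorSamples,
    n_obs: int,
    seed: int | None = None,
) -> FitReport:
    loglik = float(model.loglik_fn(map_result.theta))
    rh = rhat(samples) if samples.n_chains >= 2 else np.full(model.k, np.nan)
    flat = samples.flat()
    return FitReport(
        model_name=model_name,
        map_params=model.theta_dict(map_result.theta),
        posterior_mean={
            name: float(np.mean(flat[:, i])) for i, name in enumerate(samples.names)
        },
        percentiles=samples.percentiles(),
        rhat=dict(zip(samples.names, map(float, rh))),
        loglik_at_map=loglik,
        bic=bic(loglik, model.k, n_obs),
        n_obs=int(n_obs),
        k=model.k,
        accept_rate=[float(a) for a in samples.accept_rate],
        divergences=samples.divergences,
        seed=seed,
    )
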