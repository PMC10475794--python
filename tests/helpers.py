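"""Independent oracles for the test suite.

The joint-Gaussian oracle stacks the discrete-time model into one big
multivariate normal and evaluates densities / conditional means directly,
never touching the recursive filter code paths it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def stack_state_moments(Fs, Qs, x0, P0):
    """Means, covariances and full cross-covariances of the state sequence."""
    T = Fs.shape[0]
    d = x0.size
    means = np.zeros((T, d))
    means[0] = x0
    for k in range(1, T):
        means[k] = Fs[k] @ means[k - 1]
    cov = np.zeros((T, T, d, d))
    cov[0, 0] = P0
    for k in range(1, T):
        cov[k, k] = Fs[k] @ cov[k - 1, k - 1] @ Fs[k].T + Qs[k]
    for l in range(T):  # noqa: E741
        for k in range(l + 1, T):
            cov[k, l] = Fs[k] @ cov[k - 1, l]
            cov[l, k] = cov[k, l].T
    return means, cov


def joint_obs_moments(Fs, Qs, specs, x0, P0):
    """(mean, cov, slices) of the stacked observation vector.

    ``specs`` is a list of (H_k, m_k, R_k); steps with 0 rows are skipped.
    """
    means, cov = stack_state_moments(Fs, Qs, x0, P0)
    T = len(specs)
    sizes = [np.atleast_2d(H).shape[0] for H, _, _ in specs]
    total = sum(sizes)
    mu = np.zeros(total)
    big = np.zeros((total, total))
    offs = np.cumsum([0] + sizes)
    for k, (H, m, R) in enumerate(specs):
        H = np.atleast_2d(H)
        if H.shape[0] == 0:
            continue
        sk = slice(offs[k], offs[k + 1])
        mu[sk] = H @ means[k] + np.atleast_1d(m)
        for l in range(T):  # noqa: E741
            Hl = np.atleast_2d(specs[l][0])
            if Hl.shape[0] == 0:
                continue
            sl = slice(offs[l], offs[l + 1])
            big[sk, sl] = H @ cov[k, l] @ Hl.T
        big[sk, sk] += np.atleast_2d(R)
    return mu, big, offs


def joint_gaussian_loglik(Fs, Qs, specs, ys, x0, P0):
    mu, big, offs = joint_obs_moments(Fs, Qs, specs, x0, P0)
    yflat = np.concatenate([np.atleast_1d(y) for y in ys if np.atleast_1d(y).size])
    return float(
        multivariate_normal(mean=mu, cov=big, allow_singular=True).logpdf(yflat)
    )


def joint_smoother_means(Fs, Qs, specs, ys, x0, P0):
    """E[x_k | all observations] by direct Gaussian conditioning."""
    means, cov = stack_state_moments(Fs, Qs, x0, P0)
    mu, big, offs = joint_obs_moments(Fs, Qs, specs, x0, P0)
    T, d = means.shape
    yflat = np.concatenate([np.atleast_1d(y) for y in ys if np.atleast_1d(y).size])
    # Cov(states, obs)
    C = np.zeros((T * d, mu.size))
    for l, (H, _, _) in enumerate(specs):  # noqa: E741
        H = np.atleast_2d(H)
        if H.shape[0] == 0:
            continue
        sl = slice(offs[l], offs[l + 1])
        for k in range(T):
            C[k * d : (k + 1) * d, sl] = cov[k, l] @ H.T
    sol = np.linalg.lstsq(big, yflat - mu, rcond=None)[0]
    post = means.reshape(-1) + C @ sol
    return post.reshape(T, d)


def random_stable_system(rng, d, diffusion_rank=None):
    """Random stable LTISystem."""
    from wearssm.ssm_core import LTISystem

    A = rng.normal(size=(d, d))
    W = A - (np.abs(A).sum() + 0.5) * np.eye(d)
    r = diffusion_rank or d
    L = rng.normal(size=(d, r))
    Q = L @ L.T / r
    return LTISystem(W, Q)
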