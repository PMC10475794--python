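"""Numba kernel for the masked multichannel Kalman filter.

Kept free of Python objects so the whole predict/update recursion compiles
to machine code; this is the inner loop of every likelihood evaluation
during MAP optimization and HMC.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453


@njit(cache=True)
def kalman_core(y, mask, m, rdiag, H, Fs, Qs, x0, P0):
    """Forward filter with per-step row-deleted observations.

    y, m, rdiag : (T, p) data, deterministic observation means, noise
        variances (diagonal R); mask : (T, p) uint8, 1 = observed.
    H : (p, d) full observation matrix (rows deleted via mask).
    Fs, Qs : (T, d, d) transition/process-noise per step (index 0 unused).
    Returns (ok, loglik, step_ll, pred_m, pred_P, filt_m, filt_P).
    """
    T, p = y.shape
    d = x0.shape[0]
    x = x0.copy()
    P = P0.copy()
    ll = 0.0
    step_ll = np.zeros(T)
    pred_m = np.zeros((T, d))
    pred_P = np.zeros((T, d, d))
    filt_m = np.zeros((T, d))
    filt_P = np.zeros((T, d, d))
    eye = np.eye(d)
    for k in range(T):
        if k > 0:
            F = Fs[k]
            x = F @ x
            P = F @ P @ F.T + Qs[k]
            P = 0.5 * (P + P.T)
        pred_m[k] = x
        pred_P[k] = P

        no = 0
        for j in range(p):
            if mask[k, j]:
                no += 1
        if no == 1:
            jj = 0
            for j in range(p):
                if mask[k, j]:
                    jj = j
            h = H[jj]
            Ph = P @ h
            S = h @ Ph + rdiag[k, jj]
            if not (S > 0.0) or not np.isfinite(S):
                return False, np.nan, step_ll, pred_m, pred_P, filt_m, filt_P
            v = y[k, jj] - m[k, jj] - h @ x
            sll = -0.5 * (LOG2PI + np.log(S) + v * v / S)
            ll += sll
            step_ll[k] = sll
            K = Ph / S
            x = x + K * v
            IKH = eye - np.outer(K, h)
            P = IKH @ P @ IKH.T + rdiag[k, jj] * np.outer(K, K)
            P = 0.5 * (P + P.T)
        elif no > 1:
            Hk = np.empty((no, d))
            vk = np.empty(no)
            Rk = np.zeros((no, no))
            i = 0
            for j in range(p):
                if mask[k, j]:
                    Hk[i] = H[j]
                    vk[i] = y[k, j] - m[k, j]
                    Rk[i, i] = rdiag[k, j]
                    i += 1
            v = vk - Hk @ x
            S = Hk @ P @ Hk.T + Rk
            S = 0.5 * (S + S.T)
            ok = True
            for i in range(no):
                if not np.isfinite(S[i, i]):
                    ok = False
            if not ok:
                return False, np.nan, step_ll, pred_m, pred_P, filt_m, filt_P
            L = np.linalg.cholesky(S)
            alpha = np.linalg.solve(S, v)
            logdet = 0.0
            for i in range(no):
                logdet += np.log(L[i, i])
            sll = -0.5 * (no * LOG2PI + v @ alpha) - logdet
            ll += sll
            step_ll[k] = sll
            K = np.linalg.solve(S, Hk @ P).T
            x = x + K @ v
            IKH = eye - K @ Hk
            P = IKH @ P @ IKH.T + K @ Rk @ K.T
            P = 0.5 * (P + P.T)
        filt_m[k] = x
        filt_P[k] = P
    return True, ll, step_ll, pred_m, pred_P, filt_m, filt_P
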