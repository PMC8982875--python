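"""Compiled Kalman-filter kernel for oscillator state-space models.

The transition matrix of the oscillator model is block-diagonal with 2x2
damped-rotation blocks a_k * R(2*pi*f_k*dt), which the kernel exploits:
the predict step costs O((2K)^2) instead of O((2K)^3).  The kernel is the
inner loop of maximum-likelihood fitting and is written allocation-free;
the readable reference implementations (full filter, smoother, brute-force
Gaussian oracles) live in :mod:`oscdecomp.ssm_core` and the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def filter_loglik(cth, sth, a, q, H, tau2, y, P0):  # pragma: no cover - compiled
    """Per-time log predictive densities l_t of y under the model.

    Parameters are the per-oscillator cos/sin of the rotation angle,
    damping a_k, innovation variance sigma2_k, the J x 2K observation
    matrix, observation-noise variance tau2 and the initial (stationary)
    state covariance P0.  Returns the length-N array of l_t; their sum is
    the log marginal likelihood (prediction-error decomposition).
    """
    N, J = y.shape
    K = a.shape[0]
    n = 2 * K
    x = np.zeros(n)
    P = P0.copy()
    ll = np.empty(N)
    v = np.empty(J)
    PHt = np.empty((n, J))
    S = np.empty((J, J))
    Si = np.empty((J, J))
    G = np.empty((n, J))
    xn = np.empty(n)
    Pn = np.empty((n, n))
    for t in range(N):
        # innovation v = y_t - H x
        for j in range(J):
            s = y[t, j]
            for i in range(n):
                s -= H[j, i] * x[i]
            v[j] = s
        # PHt = P H^T ; S = H P H^T + tau2 I
        for i in range(n):
            for j in range(J):
                s = 0.0
                for m in range(n):
                    s += P[i, m] * H[j, m]
                PHt[i, j] = s
        for j in range(J):
            for j2 in range(J):
                s = 0.0
                for i in range(n):
                    s += H[j, i] * PHt[i, j2]
                S[j, j2] = s
            S[j, j] += tau2
        if J == 2:
            det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
            if det <= 0.0 or not np.isfinite(det):
                ll[t] = -np.inf
                return ll
            Si[0, 0] = S[1, 1] / det
            Si[1, 1] = S[0, 0] / det
            Si[0, 1] = -S[0, 1] / det
            Si[1, 0] = -S[1, 0] / det
            quad = (
                v[0] * (Si[0, 0] * v[0] + Si[0, 1] * v[1])
                + v[1] * (Si[1, 0] * v[0] + Si[1, 1] * v[1])
            )
            ll[t] = -0.5 * (2.0 * _LOG_2PI + np.log(det) + quad)
        elif J == 1:
            det = S[0, 0]
            if det <= 0.0 or not np.isfinite(det):
                ll[t] = -np.inf
                return ll
            Si[0, 0] = 1.0 / det
            ll[t] = -0.5 * (_LOG_2PI + np.log(det) + v[0] * v[0] / det)
        else:
            Si[:] = np.linalg.inv(S)
            sgn, logdet = np.linalg.slogdet(S)
            if sgn <= 0:
                ll[t] = -np.inf
                return ll
            quad = 0.0
            for j in range(J):
                for j2 in range(J):
                    quad += v[j] * Si[j, j2] * v[j2]
            ll[t] = -0.5 * (J * _LOG_2PI + logdet + quad)
        # gain G = PHt Si ; update x and P (P - G PHt^T, symmetrized)
        for i in range(n):
            for j in range(J):
                s = 0.0
                for j2 in range(J):
                    s += PHt[i, j2] * Si[j2, j]
                G[i, j] = s
        for i in range(n):
            s = x[i]
            for j in range(J):
                s += G[i, j] * v[j]
            xn[i] = s
        for i in range(n):
            for m in range(i, n):
                s = P[i, m]
                for j in range(J):
                    s -= G[i, j] * PHt[m, j]
                P[i, m] = s
                P[m, i] = s
        # predict: x <- F x, P <- F P F^T + Q using the 2x2 block structure
        for k in range(K):
            i0 = 2 * k
            c = a[k] * cth[k]
            s_ = a[k] * sth[k]
            x[i0] = c * xn[i0] - s_ * xn[i0 + 1]
            x[i0 + 1] = s_ * xn[i0] + c * xn[i0 + 1]
        for k in range(K):
            i0 = 2 * k
            c = a[k] * cth[k]
            s_ = a[k] * sth[k]
            for m in range(n):
                p1 = P[i0, m]
                p2 = P[i0 + 1, m]
                Pn[i0, m] = c * p1 - s_ * p2
                Pn[i0 + 1, m] = s_ * p1 + c * p2
        for k in range(K):
            m0 = 2 * k
            c = a[k] * cth[k]
            s_ = a[k] * sth[k]
            for i in range(n):
                p1 = Pn[i, m0]
                p2 = Pn[i, m0 + 1]
                P[i, m0] = c * p1 - s_ * p2
                P[i, m0 + 1] = s_ * p1 + c * p2
        for k in range(K):
            i0 = 2 * k
            P[i0, i0] += q[k]
            P[i0 + 1, i0 + 1] += q[k]
        for i in range(n):
            for m in range(i + 1, n):
                val = 0.5 * (P[i, m] + P[m, i])
                P[i, m] = val
                P[m, i] = val
    return ll
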