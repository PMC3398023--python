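"""Compiled inner EM loop.

Mirrors the pure-NumPy iteration in :mod:`timefactor.em` operation for
operation (same update order, same convergence logic); the only difference
is that the whole iterate runs inside one jitted function, which removes
the per-iteration interpreter overhead that dominates at these matrix
sizes (K of order 10).  If numba is unavailable the fitter falls back to
the NumPy loop.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the fitter
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def em_kernel(S_hat, W0, psi_e0, psi_x0, T, N, tol, max_iter, param_criterion, floor):
    """Run E/M iterations; returns (W, psi_e, psi_x, trace, converged).

    ``param_criterion`` False stops on a log-likelihood increment < tol,
    True on scale-relative change of W and psi_x < tol (with the final
    log-likelihood still appended to the trace).
    """
    K, M = W0.shape
    Km1 = K - 1
    L = M + Km1
    W = W0.copy()
    psi_e = np.empty(K)
    for k in range(K):
        psi_e[k] = psi_e0[k] if psi_e0[k] > floor else floor
    psi_x = np.empty(Km1)
    for j in range(Km1):
        psi_x[j] = psi_x0[j] if psi_x0[j] > floor else floor
    s_hat_diag = np.empty(K)
    for k in range(K):
        s_hat_diag[k] = S_hat[k, k]
    trace = np.empty(max_iter + 1)
    n_trace = 0
    converged = False
    pending = False
    base = -0.5 * N * K * np.log(2.0 * np.pi)
    prev_ll = -np.inf
    A = np.empty((K, L))
    for k in range(K):
        for j in range(Km1):
            A[k, M + j] = T[k, j]

    for it in range(max_iter + 1):
        for k in range(K):
            for m in range(M):
                A[k, m] = W[k, m]
        Ainv_psi = np.empty((K, L))
        for k in range(K):
            inv = 1.0 / psi_e[k]
            for a in range(L):
                Ainv_psi[k, a] = A[k, a] * inv
        precision = A.T @ np.ascontiguousarray(Ainv_psi)
        for m in range(M):
            precision[m, m] += 1.0
        for j in range(Km1):
            precision[M + j, M + j] += 1.0 / psi_x[j]
        finite = True
        for a in range(L):
            for b in range(L):
                if not np.isfinite(precision[a, b]):
                    finite = False
        if not finite:
            trace[n_trace] = -np.inf
            n_trace += 1
            break
        cho = np.linalg.cholesky(precision)
        sigma = np.linalg.inv(precision)
        sigma = 0.5 * (sigma + sigma.T)
        B = Ainv_psi @ sigma
        Syu = S_hat @ B
        logdet = 0.0
        for k in range(K):
            logdet += np.log(psi_e[k])
        for j in range(Km1):
            logdet += np.log(psi_x[j])
        for a in range(L):
            logdet += 2.0 * np.log(cho[a, a])
        tr = 0.0
        for k in range(K):
            tr += s_hat_diag[k] / psi_e[k]
        for k in range(K):
            for a in range(L):
                tr -= Ainv_psi[k, a] * Syu[k, a]
        ll = base - 0.5 * N * (logdet + tr)
        if it > 0:
            trace[n_trace] = ll
            n_trace += 1
        if not np.isfinite(ll):
            break
        if it > 0 and (not param_criterion) and np.isfinite(prev_ll) and ll - prev_ll < tol:
            converged = True
            break
        if pending:
            converged = True
            break
        if it == max_iter:
            break
        prev_ll = ll
        U2 = sigma + B.T @ np.ascontiguousarray(Syu)
        U2 = 0.5 * (U2 + U2.T)
        psi_x_new = np.empty(Km1)
        for j in range(Km1):
            v = U2[M + j, M + j]
            psi_x_new[j] = v if v > floor else floor
        Mzz = np.ascontiguousarray(U2[:M, :M])
        rhs = np.ascontiguousarray(Syu[:, :M]) - T @ np.ascontiguousarray(U2[M:, :M])
        W_new = np.linalg.solve(Mzz.T.copy(), rhs.T.copy()).T.copy()
        A_new = A.copy()
        for k in range(K):
            for m in range(M):
                A_new[k, m] = W_new[k, m]
        AU2 = A_new @ U2
        psi_e_new = np.empty(K)
        for k in range(K):
            v = s_hat_diag[k]
            for a in range(L):
                v += AU2[k, a] * A_new[k, a] - 2.0 * Syu[k, a] * A_new[k, a]
            psi_e_new[k] = v if v > floor else floor
        if param_criterion:
            w_scale = 1e-12
            dw = 0.0
            for k in range(K):
                for m in range(M):
                    aw = abs(W[k, m])
                    if aw > w_scale:
                        w_scale = aw
                    d = abs(W_new[k, m] - W[k, m])
                    if d > dw:
                        dw = d
            x_scale = 1e-12
            dx = 0.0
            for j in range(Km1):
                ax = abs(psi_x[j])
                if ax > x_scale:
                    x_scale = ax
                d = abs(psi_x_new[j] - psi_x[j])
                if d > dx:
                    dx = d
            if dw / w_scale < tol and dx / x_scale < tol:
                pending = True
        W, psi_e, psi_x = W_new, psi_e_new, psi_x_new
    return W, psi_e, psi_x, trace[:n_trace].copy(), converged
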