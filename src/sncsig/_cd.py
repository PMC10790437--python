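"""Weighted-least-squares coordinate descent kernel for elastic-net solvers.

Minimizes

    0.5 * sum_i u_i * (z_i - x_i' beta)^2 + lam1 * ||beta||_1
        + 0.5 * lam2 * ||beta||_2^2

by cyclic soft-thresholding with an active-set strategy.  Observation
weights ``u`` absorb any 1/n scaling.  JIT-compiled with numba when
available; a pure-numpy fallback keeps the package importable without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def _cd_sweep(X, u, r, beta, lam1, lam2, xw2, active_only):
    n, p = X.shape
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        if xw2[j] + lam2 <= 0.0:
            continue
        rho = bj * xw2[j]
        for i in range(n):
            rho += u[i] * X[i, j] * r[i]
        if rho > lam1:
            bnew = (rho - lam1) / (xw2[j] + lam2)
        elif rho < -lam1:
            bnew = (rho + lam1) / (xw2[j] + lam2)
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * d
            beta[j] = bnew
            ad = abs(d)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def cd_wls(X, u, z, beta, lam1, lam2, tol, max_iter):
    """Solve the penalized WLS problem in place; returns sweep count."""
    n, p = X.shape
    xw2 = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += u[i] * X[i, j] * X[i, j]
        xw2[j] = acc
    r = z.copy()
    for i in range(n):
        acc = 0.0
        for j in range(p):
            if beta[j] != 0.0:
                acc += X[i, j] * beta[j]
        r[i] -= acc
    sweeps = 0
    while sweeps < max_iter:
        delta = _cd_sweep(X, u, r, beta, lam1, lam2, xw2, False)
        sweeps += 1
        if delta < tol:
            break
        while sweeps < max_iter:
            delta = _cd_sweep(X, u, r, beta, lam1, lam2, xw2, True)
            sweeps += 1
            if delta < tol:
                break
    return sweeps
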