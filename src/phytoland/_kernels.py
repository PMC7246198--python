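"""Numerical kernels for the penalized solvers.

The weighted coordinate-descent sweep is the inner loop of every lasso
path fit and dominates runtime once cross-validation multiplies the work
by folds x lambdas.  When numba is available the kernel is JIT-compiled;
otherwise a numpy fallback with identical semantics is used.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _one_sweep(X, w, r, beta, xsq, lam, idx):  # pragma: no cover
    n = X.shape[0]
    delta = 0.0
    for jj in range(idx.shape[0]):
        j = idx[jj]
        bj = beta[j]
        rho = bj * xsq[j]
        for i in range(n):
            rho += w[i] * X[i, j] * r[i]
        if rho > lam:
            new = (rho - lam) / xsq[j] if xsq[j] > 0 else 0.0
        elif rho < -lam:
            new = (rho + lam) / xsq[j] if xsq[j] > 0 else 0.0
        else:
            new = 0.0
        diff = new - bj
        if diff != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * diff
            beta[j] = new
            if abs(diff) > delta:
                delta = abs(diff)
    return delta


@njit(cache=False)
def _cd_sweeps(X, w, z, beta, b0, lam, fit_intercept, tol, max_sweeps):  # pragma: no cover
    n, p = X.shape
    r = z - b0 - X @ beta
    wsum = w.sum()
    xsq = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xsq[j] = s
    all_idx = np.arange(p)
    sweeps = 0
    while sweeps < max_sweeps:
        # full sweep over every coordinate
        delta = 0.0
        if fit_intercept:
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            shift = num / wsum
            if shift != 0.0:
                for i in range(n):
                    r[i] -= shift
                b0 += shift
                if abs(shift) > delta:
                    delta = abs(shift)
        d = _one_sweep(X, w, r, beta, xsq, lam, all_idx)
        if d > delta:
            delta = d
        sweeps += 1
        if delta < tol:
            break
        # iterate on the active set until it stabilizes, then re-verify
        active = np.flatnonzero(beta)
        while sweeps < max_sweeps and active.shape[0] > 0:
            delta = 0.0
            if fit_intercept:
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                shift = num / wsum
                if shift != 0.0:
                    for i in range(n):
                        r[i] -= shift
                    b0 += shift
                    if abs(shift) > delta:
                        delta = abs(shift)
            d = _one_sweep(X, w, r, beta, xsq, lam, active)
            if d > delta:
                delta = d
            sweeps += 1
            if delta < tol:
                break
    return b0


def _cd_sweeps_numpy(X, w, z, beta, b0, lam, fit_intercept, tol, max_sweeps):
    n, p = X.shape
    r = z - b0 - X @ beta
    wsum = w.sum()
    xsq = (X * X * w[:, None]).sum(axis=0)
    wX = w[:, None] * X
    for _ in range(max_sweeps):
        delta = 0.0
        if fit_intercept:
            shift = float(np.sum(w * r) / wsum)
            if shift != 0.0:
                r -= shift
                b0 += shift
                delta = max(delta, abs(shift))
        for j in range(p):
            bj = beta[j]
            rho = float(wX[:, j] @ r) + bj * xsq[j]
            if rho > lam:
                new = (rho - lam) / xsq[j] if xsq[j] > 0 else 0.0
            elif rho < -lam:
                new = (rho + lam) / xsq[j] if xsq[j] > 0 else 0.0
            else:
                new = 0.0
            diff = new - bj
            if diff != 0.0:
                r -= X[:, j] * diff
                beta[j] = new
                delta = max(delta, abs(diff))
        if delta < tol:
            break
    return b0


def cd_sweeps(X, w, z, beta, b0, lam, fit_intercept, tol=1e-9, max_sweeps=1000):
    """Run coordinate-descent sweeps in place on ``beta``; returns the intercept."""
    if _HAVE_NUMBA:
        return float(
            _cd_sweeps(X, w, z, beta, b0, float(lam), fit_intercept, tol, max_sweeps)
        )
    return float(
        _cd_sweeps_numpy(X, w, z, beta, b0, float(lam), fit_intercept, tol, max_sweeps)
    )
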