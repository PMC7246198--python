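"""GLM family primitives shared by the penalized and Bayesian fitters.

Three error structures cover the three caterpillar responses: binomial
(survival to adult), Poisson (days to eclosion), and Gaussian (adult
weight in mg).  Each family bundles its link, inverse link, IRLS working
quantities, unit deviance, and log-likelihood kernel (terms constant in
the linear predictor are dropped, which is all the samplers need).
"""

from __future__ import annotations

import numpy as np

__all__ = ["FAMILIES", "Family", "get_family", "irls_ridge", "invlogit"]

# numerical floor for probabilities / rates
_EPS = 1e-10
_ETA_MAX = 30.0


def invlogit(eta):
    """Numerically stable logistic function."""
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    return 1.0 / (1.0 + np.exp(-eta))


class Family:
    """A GLM error structure with canonical link."""

    name: str

    def linkinv(self, eta):
        raise NotImplementedError

    def loglik(self, y, eta):
        """Log-likelihood kernel summed over observations."""
        raise NotImplementedError

    def deviance(self, y, mu):
        raise NotImplementedError

    def irls_weights(self, y, eta):
        """Return (working response z, weights w) at the current eta."""
        raise NotImplementedError

    def check_response(self, y) -> None:
        if not np.all(np.isfinite(y)):
            raise ValueError(f"{self.name} response contains non-finite values")


class Gaussian(Family):
    name = "gaussian"

    def linkinv(self, eta):
        return eta

    def loglik(self, y, eta):
        # unit variance kernel; the Bayesian sampler carries sigma separately
        return -0.5 * np.sum((y - eta) ** 2)

    def deviance(self, y, mu):
        return float(np.sum((y - mu) ** 2))

    def irls_weights(self, y, eta):
        return y, np.ones_like(eta)


class Binomial(Family):
    name = "binomial"

    def linkinv(self, eta):
        return invlogit(eta)

    def loglik(self, y, eta):
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        # y*eta - log(1+exp(eta)), stable via logaddexp
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def deviance(self, y, mu):
        mu = np.clip(mu, _EPS, 1 - _EPS)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0) + np.where(
                y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0
            )
        return float(2.0 * np.sum(term))

    def irls_weights(self, y, eta):
        mu = invlogit(eta)
        w = np.clip(mu * (1.0 - mu), _EPS, None)
        z = eta + (y - mu) / w
        return z, w

    def check_response(self, y) -> None:
        super().check_response(y)
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("binomial response must be 0/1")


class Poisson(Family):
    name = "poisson"

    def linkinv(self, eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def loglik(self, y, eta):
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        return float(np.sum(y * eta - np.exp(eta)))

    def deviance(self, y, mu):
        mu = np.clip(mu, _EPS, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        return float(2.0 * np.sum(term))

    def irls_weights(self, y, eta):
        mu = self.linkinv(eta)
        w = np.clip(mu, _EPS, None)
        z = eta + (y - mu) / w
        return z, w

    def check_response(self, y) -> None:
        super().check_response(y)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson response must be nonnegative integers")


FAMILIES = {f.name: f for f in (Gaussian(), Binomial(), Poisson())}


def get_family(name) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; expected one of {sorted(FAMILIES)}"
        ) from None


def irls_ridge(
    X: np.ndarray,
    y: np.ndarray,
    family,
    lam: float = 0.0,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Fit a GLM by iteratively reweighted least squares with an optional
    L2 penalty ``lam/2 * ||beta||^2`` on the slopes (intercept unpenalized).

    Returns ``(intercept, beta)``.  With ``lam=0`` this is the ordinary
    maximum-likelihood fit.  The penalty uses the unnormalized convention
    (summed, not mean, log-likelihood), i.e. for Gaussian data with a
    single column the solution is ``sum(xy) / (sum(x^2) + lam)``.
    """
    fam = get_family(family)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n == 0:
        raise ValueError("empty design matrix")
    fam.check_response(y)

    beta = np.zeros(p)
    # starting intercept at the link of the mean response
    mu0 = float(np.mean(y))
    if fam.name == "binomial":
        mu0 = min(max(mu0, 1e-3), 1 - 1e-3)
        b0 = float(np.log(mu0 / (1 - mu0)))
    elif fam.name == "poisson":
        b0 = float(np.log(max(mu0, 1e-3)))
    else:
        b0 = mu0

    Xa = np.column_stack([np.ones(n), X])
    pen = np.diag(np.r_[0.0, np.full(p, lam)])
    coefs = np.r_[b0, beta]
    for _ in range(max_iter):
        eta = Xa @ coefs
        z, w = fam.irls_weights(y, eta)
        XtW = Xa.T * w
        lhs = XtW @ Xa + pen
        rhs = XtW @ z
        new = np.linalg.solve(lhs, rhs)
        if np.max(np.abs(new - coefs)) < tol:
            coefs = new
            break
        coefs = new
    return float(coefs[0]), coefs[1:]
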