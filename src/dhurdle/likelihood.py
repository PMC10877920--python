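"""Log-likelihood of the dependent double-hurdle model.

Observation rule: ``y = h`` when ``min(h, w) > 0`` and 0 otherwise, with
``w = z'theta + eps`` and ``h = x'beta + v`` (linear) or
``h = exp(x'beta + v)`` (exponential); ``(eps, v)`` bivariate normal with
unit participation variance, ``Var(v) = sigma^2`` and correlation ``rho``.

Linear variant contributions (standard normal CDF ``Phi``, density ``phi``,
bivariate CDF ``Phi2``):

* zero:      ``log[1 - Phi2(z'theta, x'beta/sigma; rho)]``
* positive:  ``log Phi( (z'theta + (rho/sigma)(y - x'beta)) / sqrt(1-rho^2) )
             + log phi((y - x'beta)/sigma) - log sigma``

For the exponential variant ``exp(x'beta + v)`` is positive with
probability one, so the amount hurdle never binds: zeros contribute
``log[1 - Phi(z'theta)]`` and positives use ``log y`` in place of ``y``
with a ``-log y`` Jacobian term.  These are the only forms under which the
per-row probability mass plus the positive-part density integrate to one.

Likelihood factors for zero observations are floored at 1e-300 before the
log; the number of floored terms is surfaced so a fit can report it.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from ._bvn import bvn_cdf, bvn_pdf
from .design import DesignMatrices
from .errors import ContractError
from .params import DHParameters

LIK_FLOOR = 1e-300
_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "dh_loglik",
    "dh_loglik_terms",
    "zero_probability",
    "positive_density",
    "participation_loglik",
    "trunc_reg_loglik",
]


def _check_dims(params: DHParameters, dm: DesignMatrices) -> None:
    if params.theta.size != dm.z.shape[1]:
        raise ContractError(
            f"theta has {params.theta.size} coefficients but z has {dm.z.shape[1]} columns"
        )
    if params.beta.size != dm.X.shape[1]:
        raise ContractError(
            f"beta has {params.beta.size} coefficients but X has {dm.X.shape[1]} columns"
        )


def dh_loglik_terms(params: DHParameters, dm: DesignMatrices) -> tuple[np.ndarray, int]:
    """Per-observation log-likelihood contributions.

    Returns
    -------
    terms : ndarray, shape (n,)
    n_floored : int
        Number of zero-observation factors floored at 1e-300 before the log.
    """
    _check_dims(params, dm)
    y, z, X = dm.y, dm.z, dm.X
    theta, beta, sigma, rho = params.theta, params.beta, params.sigma, params.rho
    pos = y > 0
    a = z @ theta
    terms = np.empty(y.shape[0], dtype=float)
    n_floored = 0

    if params.variant == "linear":
        b = (X @ beta) / sigma
        if np.any(~pos):
            p0 = 1.0 - bvn_cdf(a[~pos], b[~pos], rho)
            n_floored = int(np.sum(p0 < LIK_FLOOR))
            terms[~pos] = np.log(np.maximum(p0, LIK_FLOOR))
        t = y[pos]
        jac = 0.0
    else:
        if np.any(~pos):
            terms[~pos] = log_ndtr(-a[~pos])
        t = np.log(y[pos])
        jac = t

    if np.any(pos):
        u = (t - X[pos] @ beta) / sigma
        sq = np.sqrt(1.0 - rho * rho)
        c = (a[pos] + rho * u) / sq
        terms[pos] = log_ndtr(c) - np.log(sigma) - 0.5 * _LOG2PI - 0.5 * u * u - jac
    return terms, n_floored


def dh_loglik(params: DHParameters, dm: DesignMatrices) -> float:
    """Total log-likelihood of the double-hurdle model on ``dm``."""
    terms, _ = dh_loglik_terms(params, dm)
    return float(terms.sum())


def zero_probability(params: DHParameters, z_row: np.ndarray, x_row: np.ndarray) -> float:
    """P(y = 0 | covariates): the chance that at least one hurdle fails."""
    a = float(np.dot(z_row, params.theta))
    if params.variant == "linear":
        b = float(np.dot(x_row, params.beta)) / params.sigma
        return 1.0 - bvn_cdf(a, b, params.rho)
    return float(ndtr(-a))


def positive_density(params: DHParameters, z_row: np.ndarray, x_row: np.ndarray, y) -> np.ndarray:
    """Density f(y | covariates) on the positive half-line (vectorized in y)."""
    y = np.asarray(y, dtype=float)
    a = float(np.dot(z_row, params.theta))
    mu = float(np.dot(x_row, params.beta))
    sigma, rho = params.sigma, params.rho
    sq = np.sqrt(1.0 - rho * rho)
    t = np.log(y) if params.variant == "exponential" else y
    u = (t - mu) / sigma
    dens = norm.pdf(u) / sigma * ndtr((a + rho * u) / sq)
    if params.variant == "exponential":
        dens = dens / y
    return dens


def positive_mass(params: DHParameters, z_row: np.ndarray, x_row: np.ndarray, **quad_kw) -> float:
    """Integral of the positive-part density over (0, inf) by adaptive quadrature."""
    if params.variant == "linear":
        val, _ = quad(
            lambda yy: positive_density(params, z_row, x_row, yy),
            0.0, np.inf, limit=200, **quad_kw,
        )
    else:
        # integrate in t = log y for stability
        a = float(np.dot(z_row, params.theta))
        mu = float(np.dot(x_row, params.beta))
        sq = np.sqrt(1.0 - params.rho**2)

        def integrand(t):
            u = (t - mu) / params.sigma
            return norm.pdf(u) / params.sigma * ndtr((a + params.rho * u) / sq)

        val, _ = quad(integrand, -np.inf, np.inf, limit=200, **quad_kw)
    return float(val)


# ---------------------------------------------------------------------------
# Component likelihoods (starting values; factorization identity at rho = 0)

def participation_loglik(p_participate: np.ndarray, d: np.ndarray) -> float:
    """Bernoulli log-likelihood of the hurdle-pass indicator ``d``.

    With independent errors the double-hurdle likelihood splits exactly into
    this term — evaluated at the model-implied participation probability
    ``Phi(z'theta) * Phi(x'beta/sigma)`` (linear) or ``Phi(z'theta)``
    (exponential) — plus the zero-truncated regression of positive ``y``.
    """
    p = np.clip(np.asarray(p_participate, dtype=float), LIK_FLOOR, 1.0 - 1e-16)
    d = np.asarray(d, dtype=float)
    return float(np.sum(d * np.log(p) + (1.0 - d) * np.log1p(-p)))


def trunc_reg_loglik(beta: np.ndarray, sigma: float, X_pos: np.ndarray, y_pos: np.ndarray) -> float:
    """Log-likelihood of a normal linear regression truncated at zero from below."""
    if np.any(y_pos <= 0):
        raise ContractError("truncated regression requires strictly positive outcomes")
    mu = X_pos @ np.asarray(beta, dtype=float)
    u = (y_pos - mu) / sigma
    return float(np.sum(-np.log(sigma) - 0.5 * _LOG2PI - 0.5 * u * u - log_ndtr(mu / sigma)))


# ---------------------------------------------------------------------------
# Internal objective used by the optimizer: mean negative log-likelihood and
# its analytic gradient on the unconstrained scale (theta, beta, log sigma,
# atanh rho).  Verified against numerical differentiation in the test suite.

def _unpack(p: np.ndarray, kz: int, kx: int, rho_free: bool, variant: str) -> DHParameters:
    theta = p[:kz]
    beta = p[kz:kz + kx]
    sigma = float(np.exp(p[kz + kx]))
    rho = float(np.tanh(p[kz + kx + 1])) if rho_free else 0.0
    return DHParameters(theta=theta, beta=beta, sigma=sigma, rho=rho, variant=variant)


def _pack(params: DHParameters, rho_free: bool) -> np.ndarray:
    tail = [np.log(params.sigma)]
    if rho_free:
        tail.append(np.arctanh(params.rho))
    return np.concatenate([params.theta, params.beta, tail])


def _negloglik_grad(p: np.ndarray, dm: DesignMatrices, variant: str, rho_free: bool):
    kz, kx = dm.z.shape[1], dm.X.shape[1]
    n = dm.n_obs
    params = _unpack(p, kz, kx, rho_free, variant)
    theta, beta, sigma, rho = params.theta, params.beta, params.sigma, params.rho
    y, z, X = dm.y, dm.z, dm.X
    pos = y > 0
    a = z @ theta
    sq = np.sqrt(1.0 - rho * rho)

    ll = 0.0
    g_theta = np.zeros(kz)
    g_beta = np.zeros(kx)
    g_s = 0.0
    g_r = 0.0

    z0, X0 = z[~pos], X[~pos]
    z1, X1 = z[pos], X[pos]
    a0, a1 = a[~pos], a[pos]

    if variant == "linear":
        if z0.shape[0]:
            b0 = (X0 @ beta) / sigma
            p0 = np.maximum(1.0 - bvn_cdf(a0, b0, rho), LIK_FLOOR)
            ll += np.sum(np.log(p0))
            dF_da = norm.pdf(a0) * ndtr((b0 - rho * a0) / sq)
            dF_db = norm.pdf(b0) * ndtr((a0 - rho * b0) / sq)
            g_theta += -(dF_da / p0) @ z0
            g_beta += -(dF_db / p0 / sigma) @ X0
            g_s += np.sum(dF_db * b0 / p0)
            if rho_free:
                g_r += -np.sum(bvn_pdf(a0, b0, rho) / p0) * (1.0 - rho * rho)
        t1 = y[pos]
        jac = 0.0
    else:
        if z0.shape[0]:
            ll += np.sum(log_ndtr(-a0))
            g_theta += -(np.exp(norm.logpdf(a0) - log_ndtr(-a0))) @ z0
        t1 = np.log(y[pos])
        jac = float(np.sum(t1))

    if z1.shape[0]:
        u = (t1 - X1 @ beta) / sigma
        c = (a1 + rho * u) / sq
        ll += np.sum(log_ndtr(c)) - z1.shape[0] * (np.log(sigma) + 0.5 * _LOG2PI) - 0.5 * np.sum(u * u) - jac
        mills = np.exp(norm.logpdf(c) - log_ndtr(c))
        g_theta += (mills / sq) @ z1
        g_beta += ((u - mills * rho / sq) / sigma) @ X1
        g_s += np.sum(u * u - 1.0 - mills * rho * u / sq)
        if rho_free:
            dc_dr = u / sq + rho * (a1 + rho * u) / sq**3
            g_r += np.sum(mills * dc_dr) * (1.0 - rho * rho)

    grad = np.concatenate([g_theta, g_beta, [g_s, g_r] if rho_free else [g_s]])
    return -ll / n, -grad / n
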