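"""Maximum-likelihood fitting and inference for the double-hurdle model.

The estimation strategy follows standard practice for this model family:

1. starting values from a probit of the participation indicator on ``z``
   and a zero-truncated normal regression (linear variant) or an OLS of
   ``log y`` (exponential variant) on the positive subsample, with rho = 0;
2. quasi-Newton (BFGS) maximization of the joint likelihood over the
   unconstrained parameterization (theta, beta, log sigma, atanh rho),
   with an analytic gradient;
3. standard errors from the inverse observed information (numerical
   Hessian of the negative log-likelihood), delta method for sigma and rho.

``fit_dh`` is the functional entry point; :class:`dhurdle.DoubleHurdle`
wraps it in a scikit-learn estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import chi2, norm
from statsmodels.discrete.discrete_model import Probit
from statsmodels.tools.numdiff import approx_hess3
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .design import DesignMatrices
from .errors import ContractError, DegenerateDataError
from .likelihood import _negloglik_grad, _pack, _unpack, dh_loglik_terms, positive_density
from .params import DHFitResult, DHParameters, WaldRho

__all__ = [
    "fit_dh",
    "probit_fit",
    "trunc_reg_fit",
    "wald_rho_test",
    "lr_test",
    "pseudo_r2",
    "predict_participation",
    "predict_expected_y",
]


def probit_fit(z: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Probit MLE of a binary indicator ``d`` on covariates ``z``.

    Falls back to an L1-penalized fit (tiny penalty) with a warning when the
    data are perfectly separated, so downstream starting values stay finite.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.min() == d.max():
        raise DegenerateDataError("participation indicator takes a single value")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # imperfect convergence is fine here: these are starting values
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = Probit(d, z).fit(disp=0, maxiter=500)
        theta = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e4:
            raise PerfectSeparationError("non-finite or exploding probit coefficients")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        warnings.warn(
            "perfect separation in the participation probit; using a penalized fit",
            stacklevel=2,
        )
        res = Probit(d, z).fit_regularized(alpha=1e-2, disp=0, maxiter=500)
        theta = np.asarray(res.params, dtype=float)
    return theta


def _truncreg_negll_grad(p: np.ndarray, X: np.ndarray, y: np.ndarray):
    k = X.shape[1]
    beta, s = p[:k], p[k]
    sigma = np.exp(s)
    mu = X @ beta
    b = mu / sigma
    u = (y - mu) / sigma
    mills = np.exp(norm.logpdf(b) - norm.logcdf(b))
    ll = np.sum(-s - 0.5 * np.log(2 * np.pi) - 0.5 * u * u - norm.logcdf(b))
    g_beta = ((u - mills) / sigma) @ X
    g_s = np.sum(u * u - 1.0 + mills * b)
    n = y.shape[0]
    return -ll / n, -np.concatenate([g_beta, [g_s]]) / n


def trunc_reg_fit(X_pos: np.ndarray, y_pos: np.ndarray) -> tuple[np.ndarray, float]:
    """MLE of a normal regression truncated at zero: returns (beta, sigma)."""
    X_pos = np.asarray(X_pos, dtype=float)
    y_pos = np.asarray(y_pos, dtype=float)
    if np.any(y_pos <= 0):
        raise ContractError("truncated regression requires strictly positive outcomes")
    beta0, *_ = np.linalg.lstsq(X_pos, y_pos, rcond=None)
    resid = y_pos - X_pos @ beta0
    s0 = np.log(max(resid.std(), 1e-6))
    res = minimize(
        _truncreg_negll_grad, np.concatenate([beta0, [s0]]),
        args=(X_pos, y_pos), jac=True, method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    k = X_pos.shape[1]
    return res.x[:k], float(np.exp(res.x[k]))


def _start_values(dm: DesignMatrices, variant: str) -> DHParameters:
    pos = dm.y > 0
    theta0 = probit_fit(dm.z, dm.d)
    if variant == "linear":
        beta0, sigma0 = trunc_reg_fit(dm.X[pos], dm.y[pos])
    else:
        t = np.log(dm.y[pos])
        beta0, *_ = np.linalg.lstsq(dm.X[pos], t, rcond=None)
        sigma0 = max(float((t - dm.X[pos] @ beta0).std()), 1e-6)
    return DHParameters(theta=theta0, beta=beta0, sigma=sigma0, rho=0.0, variant=variant)


def fit_dh(
    dm: DesignMatrices,
    variant: str = "linear",
    rho_mode: str = "free",
    *,
    start: DHParameters | None = None,
    gtol: float = 1e-8,
    max_iter: int = 500,
    compute_null: bool = True,
    compute_se: bool = True,
) -> DHFitResult:
    """Fit the double-hurdle model by maximum likelihood.

    Parameters
    ----------
    dm : DesignMatrices
        Aligned z, X, y (must contain both zero and positive outcomes).
    variant : {"linear", "exponential"}
    rho_mode : {"free", "fixed_zero"}
        Estimate the error correlation or pin it at zero (Cragg's
        independent model).
    compute_null : bool
        Also fit the intercept-only model (same variant and rho mode) to
        report the likelihood-ratio statistic and McFadden pseudo-R2.
    compute_se : bool
        Compute the observed-information covariance matrix; simulation
        loops that only need point estimates can switch it off.
    """
    if rho_mode not in ("free", "fixed_zero"):
        raise ContractError(f"rho_mode must be 'free' or 'fixed_zero', got {rho_mode!r}")
    n_zero = int(np.sum(dm.y == 0))
    if n_zero == 0:
        raise DegenerateDataError(
            "no zero outcomes: the participation hurdle is uninformative; "
            "fit a truncated regression instead"
        )
    if n_zero == dm.n_obs:
        raise DegenerateDataError(
            "no positive outcomes: the expenditure hurdle is uninformative; "
            "fit a probit instead"
        )

    rho_free = rho_mode == "free"
    start = start if start is not None else _start_values(dm, variant)
    kz, kx = dm.z.shape[1], dm.X.shape[1]

    def _minimize(p0, free):
        return minimize(
            _negloglik_grad, p0, args=(dm, variant, free), jac=True,
            method="BFGS", options={"gtol": gtol, "maxiter": max_iter},
        )

    # Stage 1: independent-errors fit (also the final fit when rho is pinned).
    res0 = _minimize(_pack(start, False), False)
    n_iter = int(res0.nit)
    if not rho_free:
        res = res0
    else:
        # Free-rho fit from the raw starting values rather than from the
        # stage-1 solution: the rho-score vanishes identically at the
        # independent-model MLE (a known degeneracy of this model family),
        # so BFGS started exactly there can never move rho off zero.
        res = _minimize(_pack(start, True), True)
        n_iter += int(res.nit)
        if res.fun > res0.fun + 1e-10:
            # The free fit must nest the independent one; kick rho and retry.
            for r0 in (0.3, -0.3):
                cand = _minimize(np.concatenate([res0.x, [np.arctanh(r0)]]), True)
                n_iter += int(cand.nit)
                if cand.fun < res.fun:
                    res = cand
    gmax = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or gmax < gtol)
    if not converged:
        warnings.warn(
            f"double-hurdle fit did not converge (max |grad| = {gmax:.2e})", stacklevel=2
        )
    params = _unpack(res.x, kz, kx, rho_free, variant)
    loglik = -float(res.fun) * dm.n_obs
    _, n_floored = dh_loglik_terms(params, dm)
    if n_floored:
        warnings.warn(f"{n_floored} likelihood terms floored at 1e-300", stacklevel=2)

    vcov = None
    se = None
    if compute_se:
        n = dm.n_obs

        def total_negll(p):
            return _negloglik_grad(p, dm, variant, rho_free)[0] * n

        H = approx_hess3(res.x, total_negll)
        H = 0.5 * (H + H.T)
        try:
            V = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            V = np.linalg.pinv(H)
        # delta method back to (theta, beta, sigma, rho)
        jdiag = np.ones(V.shape[0])
        jdiag[kz + kx] = params.sigma
        if rho_free:
            jdiag[kz + kx + 1] = 1.0 - params.rho**2
        vcov = (jdiag[:, None] * V) * jdiag[None, :]
        vcov = 0.5 * (vcov + vcov.T)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    loglik_null = lr_chi2 = lr_df = lr_p = pr2 = None
    if compute_null:
        dm_null = DesignMatrices(
            z=np.ones((dm.n_obs, 1)), X=np.ones((dm.n_obs, 1)), y=dm.y,
            z_names=["const"], x_names=["const"],
        )
        null_fit = fit_dh(
            dm_null, variant=variant, rho_mode=rho_mode,
            compute_null=False, compute_se=False,
        )
        loglik_null = null_fit.loglik
        lr_df = (kz - 1) + (kx - 1)
        lr_chi2 = max(0.0, 2.0 * (loglik - loglik_null))
        lr_p = float(chi2.sf(lr_chi2, lr_df)) if lr_df > 0 else float("nan")
        pr2 = 1.0 - loglik / loglik_null if loglik_null < 0 else float("nan")

    wald = None
    if rho_free and se is not None:
        wald = _wald_rho(params.rho, float(se[-1]), scale="atanh")

    names = [f"participation:{c}" for c in dm.z_names] + [f"expenditure:{c}" for c in dm.x_names]
    names.append("sigma")
    if rho_free:
        names.append("rho")

    return DHFitResult(
        params=params, vcov=vcov, loglik=loglik, loglik_null=loglik_null,
        lr_chi2=lr_chi2, lr_df=lr_df, lr_p=lr_p, pseudo_r2=pr2, wald_rho=wald,
        converged=converged, n_iter=n_iter, n_obs=dm.n_obs, n_zero=n_zero,
        rho_mode=rho_mode, se=se, param_names=names, n_floored=n_floored,
    )


def _wald_rho(rho: float, se_rho: float, scale: str) -> WaldRho:
    if rho == 0.0:
        return WaldRho(statistic=0.0, df=1, p_value=1.0)
    if se_rho <= 0.0:
        return WaldRho(statistic=float("inf"), df=1, p_value=0.0)
    if scale == "atanh":
        stat = (np.arctanh(rho) * (1.0 - rho * rho) / se_rho) ** 2
    elif scale == "rho":
        stat = (rho / se_rho) ** 2
    else:
        raise ContractError(f"unknown Wald scale {scale!r}")
    return WaldRho(statistic=float(stat), df=1, p_value=float(chi2.sf(stat, 1)))


def wald_rho_test(fit: DHFitResult, scale: str = "atanh") -> WaldRho:
    """Wald chi-square(1) test of independent hurdle errors (H0: rho = 0).

    By default the statistic is formed on the Fisher-z (atanh rho) scale —
    the parameterization the likelihood is maximized on, and the one
    standard survey-econometrics software reports.  The z-scale statistic
    is better calibrated in moderate samples than the natural-scale
    ``(rho / SE(rho))^2`` form, which remains available as ``scale="rho"``.
    Both are asymptotically equivalent under H0.
    """
    if fit.rho_mode != "free":
        raise ContractError("Wald test of rho requires a fit with rho_mode='free'")
    if fit.vcov is None or fit.se is None:
        raise ContractError("fit carries no covariance matrix; refit with compute_se=True")
    return _wald_rho(fit.params.rho, float(fit.se[-1]), scale)


def lr_test(fit_full: DHFitResult, fit_null: DHFitResult) -> dict:
    """Likelihood-ratio test of a nested null fit against a full fit."""
    if fit_full.n_obs != fit_null.n_obs or fit_full.n_zero != fit_null.n_zero:
        raise ContractError("LR test requires both fits on the same data")
    if fit_full.params.variant != fit_null.params.variant:
        raise ContractError("LR test requires the same outcome variant")
    df = (fit_full.params.theta.size + fit_full.params.beta.size) - (
        fit_null.params.theta.size + fit_null.params.beta.size
    )
    if df < 0:
        raise ContractError("null model has more parameters than the full model")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-8:
        raise ContractError("null log-likelihood exceeds the full one; models are not nested")
    stat = max(0.0, stat)
    return {"chi2": stat, "df": df, "p": float(chi2.sf(stat, df)) if df > 0 else float("nan")}


def pseudo_r2(fit: DHFitResult) -> float:
    """McFadden pseudo-R2: 1 - loglik / loglik_null."""
    if fit.loglik_null is None:
        raise ContractError("fit has no null log-likelihood; refit with compute_null=True")
    return 1.0 - fit.loglik / fit.loglik_null


def predict_participation(params: DHParameters, z: np.ndarray) -> np.ndarray:
    """First-hurdle probability P(w > 0) = Phi(z'theta), rowwise."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != params.theta.size:
        raise ContractError("z has the wrong number of columns")
    out = ndtr(z @ params.theta)
    return out if out.size > 1 else float(out[0])


def _expected_y_closed_form(params: DHParameters, a: float, mu: float) -> float:
    sigma, rho = params.sigma, params.rho
    if params.variant == "exponential":
        return float(np.exp(mu + 0.5 * sigma**2) * ndtr(a + rho * sigma))
    if rho == 0.0:
        b = mu / sigma
        return float(ndtr(a) * (mu * ndtr(b) + sigma * norm.pdf(b)))
    raise ValueError("no closed form for the linear variant with rho != 0")


def predict_expected_y(
    params: DHParameters, z_row: np.ndarray, x_row: np.ndarray, method: str = "auto"
) -> float:
    """Unconditional mean E[y | covariates] (zeros included).

    ``method='quad'`` integrates ``y f(y)`` over the positive half-line by
    adaptive quadrature — the defining computation.  ``'auto'`` substitutes
    the exact closed form where one exists (linear with rho = 0;
    exponential for any rho), falling back to quadrature otherwise.
    """
    z_row = np.asarray(z_row, dtype=float).ravel()
    x_row = np.asarray(x_row, dtype=float).ravel()
    if z_row.size != params.theta.size or x_row.size != params.beta.size:
        raise ContractError("covariate rows do not match coefficient lengths")
    a = float(z_row @ params.theta)
    mu = float(x_row @ params.beta)
    if method == "auto":
        try:
            return _expected_y_closed_form(params, a, mu)
        except ValueError:
            pass
    elif method == "closed_form":
        return _expected_y_closed_form(params, a, mu)
    elif method != "quad":
        raise ContractError(f"unknown method {method!r}")

    if params.variant == "linear":
        val, _ = quad(
            lambda yy: yy * positive_density(params, z_row, x_row, yy),
            0.0, np.inf, limit=200,
        )
    else:
        sq = np.sqrt(1.0 - params.rho**2)

        def integrand(t):
            u = (t - mu) / params.sigma
            return np.exp(t) * norm.pdf(u) / params.sigma * ndtr((a + params.rho * u) / sq)

        val, _ = quad(integrand, mu - 12 * params.sigma, mu + 12 * params.sigma, limit=200)
    return float(max(val, 0.0))
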