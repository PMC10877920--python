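"""Scikit-learn estimator interface to the double-hurdle model."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .design import DesignMatrices
from .errors import DataError
from .model import fit_dh, predict_expected_y, predict_participation

__all__ = ["DoubleHurdle"]


class DoubleHurdle(BaseEstimator, RegressorMixin):
    """Cragg double-hurdle regressor for a non-negative outcome with exact zeros.

    A probit participation hurdle and a truncated-normal (``variant='linear'``)
    or lognormal (``variant='exponential'``) expenditure hurdle are estimated
    jointly by maximum likelihood, optionally with correlated latent errors.

    Parameters
    ----------
    variant : {"linear", "exponential"}, default "linear"
        Functional form of the expenditure equation.
    rho : {"free", "fixed_zero"}, default "free"
        Estimate the error correlation, or fix it at zero (independent
        hurdles, Cragg's original model).
    fit_intercept : bool, default True
        Prepend a constant column to both hurdles.  Disable when the design
        matrices already carry one.
    compute_null : bool, default True
        Fit the intercept-only reference model to report ``lr_chi2_`` and
        ``pseudo_r2_``.
    gtol : float, default 1e-8
        Gradient max-norm tolerance of the BFGS maximizer (per-observation
        scale).
    max_iter : int, default 500

    Attributes
    ----------
    theta_ : ndarray of shape (k_z,)
        Participation coefficients.
    beta_ : ndarray of shape (k_x,)
        Expenditure coefficients.
    sigma_, rho_ : float
        Error scale of the expenditure equation and error correlation.
    vcov_ : ndarray
        Covariance of (theta, beta, sigma[, rho]) from the observed
        information.
    loglik_, loglik_null_, lr_chi2_, pseudo_r2_ : float
        Fit and goodness-of-fit summaries.
    wald_rho_ : WaldRho
        Wald test of independent errors (``rho='free'`` only).
    result_ : DHFitResult
        The full fit object.

    Examples
    --------
    >>> import numpy as np
    >>> from dhurdle import DoubleHurdle
    >>> rng = np.random.default_rng(0)
    >>> x = rng.binomial(1, 0.5, 4000).astype(float)
    >>> eps, v = rng.standard_normal(4000), rng.standard_normal(4000)
    >>> h = 1.0 + x + 1.5 * v
    >>> y = np.where((0.3 + 0.8 * x + eps > 0) & (h > 0), h, 0.0)
    >>> m = DoubleHurdle(variant="linear", rho="fixed_zero").fit(x[:, None], y)
    >>> m.theta_.shape, m.beta_.shape
    ((2,), (2,))
    """

    def __init__(
        self,
        variant: str = "linear",
        rho: str = "free",
        fit_intercept: bool = True,
        compute_null: bool = True,
        gtol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.variant = variant
        self.rho = rho
        self.fit_intercept = fit_intercept
        self.compute_null = compute_null
        self.gtol = gtol
        self.max_iter = max_iter

    def _design(self, X, Z, y=None):
        if y is not None:
            X, y = check_X_y(X, y, y_numeric=True)
            if np.any(y < 0):
                raise DataError("outcome must be non-negative")
        else:
            X = check_array(X)
        Z = X if Z is None else check_array(Z)
        if Z.shape[0] != X.shape[0]:
            raise DataError("Z and X must have the same number of rows")
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            Z = np.column_stack([np.ones(Z.shape[0]), Z])
        return X, Z, y

    def fit(self, X, y, Z=None):
        """Fit the model.

        Parameters
        ----------
        X : array-like of shape (n, k_x)
            Expenditure covariates.
        y : array-like of shape (n,)
            Non-negative outcome with exact zeros for non-participants.
        Z : array-like of shape (n, k_z), optional
            Participation covariates; defaults to ``X``.
        """
        Xd, Zd, y = self._design(X, Z, y)
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else Xd.shape[1]
        names_x = [f"x{j}" for j in range(Xd.shape[1])]
        names_z = [f"z{j}" for j in range(Zd.shape[1])]
        if self.fit_intercept:
            names_x[0] = names_z[0] = "const"
        dm = DesignMatrices(z=Zd, X=Xd, y=y, z_names=names_z, x_names=names_x)
        res = fit_dh(
            dm,
            variant=self.variant,
            rho_mode=self.rho,
            gtol=self.gtol,
            max_iter=self.max_iter,
            compute_null=self.compute_null,
        )
        self.result_ = res
        self.theta_ = res.params.theta
        self.beta_ = res.params.beta
        self.sigma_ = res.params.sigma
        self.rho_ = res.params.rho
        self.vcov_ = res.vcov
        self.se_ = res.se
        self.loglik_ = res.loglik
        self.loglik_null_ = res.loglik_null
        self.lr_chi2_ = res.lr_chi2
        self.pseudo_r2_ = res.pseudo_r2
        self.wald_rho_ = res.wald_rho
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.n_obs_ = res.n_obs
        self.n_zero_ = res.n_zero
        return self

    def predict(self, X, Z=None):
        """Expected outcome E[y | covariates], zeros included."""
        check_is_fitted(self, "result_")
        Xd, Zd, _ = self._design(X, Z)
        return np.array(
            [
                predict_expected_y(self.result_.params, Zd[i], Xd[i])
                for i in range(Xd.shape[0])
            ]
        )

    def predict_participation(self, Z):
        """First-hurdle probability Phi(z'theta) per row."""
        check_is_fitted(self, "result_")
        Zd = check_array(Z)
        if self.fit_intercept:
            Zd = np.column_stack([np.ones(Zd.shape[0]), Zd])
        return np.atleast_1d(predict_participation(self.result_.params, Zd))
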