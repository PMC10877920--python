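"""Parameter and result containers for the double-hurdle model.

The model has two latent equations.  Participation (first hurdle):

    w_i = z_i' theta + eps_i,        eps_i ~ N(0, 1)

and the expenditure level (second hurdle), either linear

    h_i = x_i' beta + v_i,           v_i ~ N(0, sigma^2)

or exponential, h_i = exp(x_i' beta + v_i).  The observed outcome is

    y_i = h_i   if min(h_i, w_i) > 0,   else 0,

with corr(eps_i, v_i) = rho.  ``DHParameters`` is the single home of
(theta, beta, sigma, rho, variant); everything downstream consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ContractError, ParameterDomainError

Variant = Literal["linear", "exponential"]
VARIANTS = ("linear", "exponential")


@dataclass
class DHParameters:
    """True or estimated parameters of a double-hurdle model.

    Attributes
    ----------
    theta : ndarray, shape (k_z,)
        Participation (probit) coefficients, one per column of ``z``.
    beta : ndarray, shape (k_x,)
        Expenditure coefficients, one per column of ``X``.
    sigma : float
        Standard deviation of the expenditure error ``v``; strictly positive.
    rho : float
        Correlation between the two latent errors, in (-1, 1).
    variant : {"linear", "exponential"}
        Second-hurdle functional form.
    """

    theta: np.ndarray
    beta: np.ndarray
    sigma: float
    rho: float = 0.0
    variant: Variant = "linear"

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.theta.ndim != 1 or self.beta.ndim != 1:
            raise ContractError("theta and beta must be 1-D coefficient vectors")
        self.sigma = float(self.sigma)
        self.rho = float(self.rho)
        if not np.isfinite(self.sigma) or self.sigma <= 0.0:
            raise ParameterDomainError(f"sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.rho) or abs(self.rho) >= 1.0:
            raise ParameterDomainError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.variant not in VARIANTS:
            raise ParameterDomainError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def n_params(self) -> int:
        return self.theta.size + self.beta.size + 2

    def as_array(self) -> np.ndarray:
        """Stack as (theta, beta, sigma, rho) — the order used by vcov."""
        return np.concatenate([self.theta, self.beta, [self.sigma, self.rho]])


@dataclass
class WaldRho:
    """Wald chi-square test of H0: rho = 0 (independent hurdle errors)."""

    statistic: float
    df: int
    p_value: float


@dataclass
class DHFitResult:
    """Everything produced by a maximum-likelihood double-hurdle fit.

    ``vcov`` is ordered as (theta..., beta..., sigma[, rho]) on the natural
    scale (delta method applied to the internal log-sigma / atanh-rho
    parameterization).  ``loglik_null`` refers to the intercept-only model of
    the same variant and rho mode, so ``lr_chi2 = 2 (loglik - loglik_null)``
    and McFadden's pseudo-R2 is ``1 - loglik / loglik_null``.
    """

    params: DHParameters
    vcov: np.ndarray
    loglik: float
    loglik_null: float | None
    lr_chi2: float | None
    lr_df: int | None
    lr_p: float | None
    pseudo_r2: float | None
    wald_rho: WaldRho | None
    converged: bool
    n_iter: int
    n_obs: int
    n_zero: int
    rho_mode: str
    se: np.ndarray = field(default=None, repr=False)
    param_names: list[str] = field(default_factory=list)
    n_floored: int = 0

    @property
    def n_positive(self) -> int:
        return self.n_obs - self.n_zero
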