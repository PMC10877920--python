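"""Standard bivariate normal CDF and PDF.

The double-hurdle likelihood needs :math:`\\Phi_2(h, k; \\rho)`, the
probability that two standard normal variates with correlation ``rho`` fall
below ``h`` and ``k`` respectively.  It is computed from Owen's T function

.. math::

    \\Phi_2(h, k; \\rho) = \\tfrac12\\bigl(\\Phi(h) + \\Phi(k)\\bigr)
        - T(h, a_h) - T(k, a_k) - \\delta_{hk},

with :math:`a_h = (k - \\rho h)/(h\\sqrt{1-\\rho^2})` (and symmetrically for
``a_k``), and :math:`\\delta_{hk} = \\tfrac12` when ``h`` and ``k`` lie on
opposite sides of zero.  ``scipy.special.owens_t`` evaluates T to close to
machine precision, so the absolute error of this routine is well inside the
1e-10 contract required by the likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bvn_pdf"]


def _owen_term(h: np.ndarray, other: np.ndarray, rho: np.ndarray, root: np.ndarray) -> np.ndarray:
    """T(h, (other - rho*h)/(h*root)) with the h -> 0 limit handled."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        a = (other - rho * h) / (h * root)
    # h == 0: the limit of T(h, a) is sign(other)/4 (T(0, +-inf) = +-1/4).
    lim = np.where(other > 0.0, np.inf, np.where(other < 0.0, -np.inf, 0.0))
    a = np.where(h == 0.0, lim, a)
    out = owens_t(h, a)
    out = np.where((h == 0.0) & (other == 0.0), 0.0, out)
    return out


def bvn_cdf(h, k, rho):
    """Bivariate standard normal CDF ``P(H <= h, K <= k)`` at correlation rho.

    Parameters
    ----------
    h, k : array_like
        Upper integration limits; broadcast against each other.
    rho : array_like
        Correlation(s) in [-1, 1].

    Returns
    -------
    ndarray or float
        Probabilities in [0, 1].
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float), np.asarray(rho, dtype=float)
    )
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("correlation must lie in [-1, 1]")

    out = np.empty(h.shape, dtype=float)

    degenerate = np.abs(rho) == 1.0
    if np.any(degenerate):
        pos = degenerate & (rho > 0)
        neg = degenerate & (rho < 0)
        out[pos] = ndtr(np.minimum(h, k))[pos]
        out[neg] = np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)[neg]

    reg = ~degenerate
    if np.any(reg):
        hr, kr, rr = h[reg], k[reg], rho[reg]
        root = np.sqrt(1.0 - rr * rr)
        both_zero = (hr == 0.0) & (kr == 0.0)
        t_h = _owen_term(hr, kr, rr, root)
        t_k = _owen_term(kr, hr, rr, root)
        # sign arithmetic, not the product hk itself: that can underflow to 0
        sh, sk = np.sign(hr), np.sign(kr)
        delta = np.where((sh * sk < 0.0) | ((sh * sk == 0.0) & (sh + sk < 0.0)), 0.5, 0.0)
        val = 0.5 * (ndtr(hr) + ndtr(kr)) - t_h - t_k - delta
        # Origin: closed form, avoids the 0/0 in both Owen terms.
        val = np.where(both_zero, 0.25 + np.arcsin(rr) / (2.0 * np.pi), val)
        out[reg] = np.clip(val, 0.0, 1.0)

    if out.ndim == 0:
        return float(out)
    return out


def bvn_pdf(h, k, rho):
    """Bivariate standard normal density at ``(h, k)`` with correlation rho."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    omr2 = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / omr2
    val = np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(omr2))
    if val.ndim == 0:
        return float(val)
    return val
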