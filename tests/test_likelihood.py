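"""Double-hurdle log-likelihood: closed-form cases, gradient, invariances."""

import numpy as np
import pytest
from statsmodels.tools.numdiff import approx_fprime

from dhurdle import (
    DesignMatrices,
    DHParameters,
    dh_loglik,
    dh_loglik_terms,
    encode_design,
    simulate_households,
)
from dhurdle.errors import ContractError
from dhurdle.likelihood import (
    _negloglik_grad,
    participation_loglik,
    trunc_reg_loglik,
)
from scipy.special import ndtr

from conftest import binary_config


def _dm(y, z=None, X=None):
    y = np.asarray(y, dtype=float)
    n = y.size
    z = np.ones((n, 1)) if z is None else z
    X = np.ones((n, 1)) if X is None else X
    return DesignMatrices(z=z, X=X, y=y, z_names=["c"], x_names=["c"])


def test_zero_observation_closed_form():
    """ztheta = xbeta = 0, sigma=1, rho=0: P(y=0) = 1 - 1/2 * 1/2 = 3/4."""
    params = DHParameters(theta=[0.0], beta=[0.0], sigma=1.0, rho=0.0)
    assert dh_loglik(params, _dm([0.0])) == pytest.approx(np.log(0.75), abs=1e-12)


def test_certain_participation_modal_residual():
    params = DHParameters(theta=[30.0], beta=[2.0], sigma=1.0, rho=0.0)
    assert dh_loglik(params, _dm([2.0])) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_exponential_zero_term_is_first_hurdle_only():
    params = DHParameters(theta=[0.5], beta=[0.0], sigma=1.0, rho=0.3, variant="exponential")
    assert dh_loglik(params, _dm([0.0])) == pytest.approx(np.log(ndtr(-0.5)), abs=1e-12)


@pytest.mark.parametrize("variant,rho_free", [("linear", True), ("linear", False), ("exponential", True)])
def test_analytic_gradient_matches_numerical(variant, rho_free):
    cfg = binary_config(
        300, seed=3, rho=0.5 if variant == "linear" else 0.4, variant=variant,
        beta=(2.0, 1.0) if variant == "linear" else (1.0, 0.5),
        sigma=1.5 if variant == "linear" else 0.8,
    )
    dm = encode_design(simulate_households(cfg), cfg.design)
    p0 = np.array([0.4, -0.5, 1.5, 0.8, np.log(1.2)] + ([np.arctanh(0.3)] if rho_free else []))
    _, g = _negloglik_grad(p0, dm, variant, rho_free)
    g_num = approx_fprime(p0, lambda q: _negloglik_grad(q, dm, variant, rho_free)[0], centered=True)
    assert np.max(np.abs(g - g_num)) < 1e-7


def test_rho_zero_factorizes_into_participation_and_truncreg(small_table):
    """With independent errors the likelihood splits into the hurdle-pass
    Bernoulli part (p = Phi(z'theta) Phi(x'beta/sigma)) plus the
    zero-truncated regression of the positives."""
    table, cfg = small_table
    dm = encode_design(table, cfg.design)
    params = DHParameters(theta=[0.4, -0.6], beta=[1.8, 1.2], sigma=1.4, rho=0.0)
    p_pass = ndtr(dm.z @ params.theta) * ndtr((dm.X @ params.beta) / params.sigma)
    pos = dm.y > 0
    split = participation_loglik(p_pass, dm.d) + trunc_reg_loglik(
        params.beta, params.sigma, dm.X[pos], dm.y[pos]
    )
    assert dh_loglik(params, dm) == pytest.approx(split, abs=1e-8)


def test_loglik_permutation_invariant(small_table):
    table, cfg = small_table
    dm = encode_design(table, cfg.design)
    perm = np.random.default_rng(2).permutation(dm.n_obs)
    dm_p = DesignMatrices(z=dm.z[perm], X=dm.X[perm], y=dm.y[perm],
                          z_names=dm.z_names, x_names=dm.x_names)
    params = cfg.true_params
    assert dh_loglik(params, dm) == pytest.approx(dh_loglik(params, dm_p), abs=1e-10)


def test_dimension_mismatch_raises():
    params = DHParameters(theta=[0.0, 1.0], beta=[0.0], sigma=1.0, rho=0.0)
    with pytest.raises(ContractError):
        dh_loglik(params, _dm([0.0]))


def test_extreme_parameters_floor_not_nan():
    """A zero observation that is almost impossible under the parameters is
    floored, counted, and keeps the total finite."""
    params = DHParameters(theta=[30.0], beta=[40.0], sigma=1.0, rho=0.0)
    terms, n_floored = dh_loglik_terms(params, _dm([0.0]))
    assert np.isfinite(terms).all()
    assert n_floored == 1


def test_jacobian_term_for_exponential_variant():
    """The exponential positive-part contribution is the lognormal density:
    scaling y multiplies the likelihood by 1/scale at matched parameters."""
    p1 = DHParameters(theta=[5.0], beta=[0.0], sigma=1.0, rho=0.0, variant="exponential")
    p2 = DHParameters(theta=[5.0], beta=[np.log(10.0)], sigma=1.0, rho=0.0, variant="exponential")
    ll1 = dh_loglik(p1, _dm([1.0]))
    ll2 = dh_loglik(p2, _dm([10.0]))
    assert ll2 == pytest.approx(ll1 - np.log(10.0), abs=1e-10)
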