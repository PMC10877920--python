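"""Wald/LR tests, pseudo-R2, and model predictions."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from dhurdle import (
    DHFitResult,
    DHParameters,
    encode_design,
    fit_dh,
    lr_test,
    predict_expected_y,
    predict_participation,
    pseudo_r2,
    simulate_households,
    wald_rho_test,
)
from dhurdle.errors import ContractError

from conftest import binary_config


def _result(rho=0.2, se_rho=0.1, loglik=-5700.0, loglik_null=-5800.0, k=1):
    params = DHParameters(theta=np.zeros(k), beta=np.zeros(k), sigma=1.0, rho=rho)
    se = np.concatenate([np.full(2 * k + 1, 0.1), [se_rho]])
    return DHFitResult(
        params=params, vcov=np.eye(2 * k + 2), loglik=loglik, loglik_null=loglik_null,
        lr_chi2=None, lr_df=None, lr_p=None, pseudo_r2=None, wald_rho=None,
        converged=True, n_iter=1, n_obs=100, n_zero=30, rho_mode="free", se=se,
        param_names=["participation:const", "expenditure:const", "sigma", "rho"][: 2 * k + 2],
    )


def test_wald_statistic_closed_form():
    w = wald_rho_test(_result(rho=0.2, se_rho=0.1), scale="rho")
    assert w.statistic == pytest.approx(4.0, abs=1e-12)
    assert w.p_value == pytest.approx(0.0455, abs=2e-4)


def test_wald_default_uses_fisher_z_scale():
    rho, se = 0.2, 0.1
    w = wald_rho_test(_result(rho=rho, se_rho=se))
    expected = (np.arctanh(rho) * (1 - rho**2) / se) ** 2
    assert w.statistic == pytest.approx(expected, rel=1e-12)
    # the two scales agree to first order near rho = 0
    tiny = wald_rho_test(_result(rho=0.01, se_rho=0.1))
    assert tiny.statistic == pytest.approx(0.01, abs=1e-4)


def test_wald_zero_rho_gives_p_one():
    w = wald_rho_test(_result(rho=0.0, se_rho=0.1))
    assert w.statistic == 0.0 and w.p_value == 1.0


def test_wald_requires_free_rho_and_vcov():
    res = _result()
    res.rho_mode = "fixed_zero"
    with pytest.raises(ContractError):
        wald_rho_test(res)
    res2 = _result()
    res2.vcov = None
    with pytest.raises(ContractError):
        wald_rho_test(res2)


def test_lr_and_pseudo_r2_arithmetic():
    full = _result(loglik=-5700.0)
    null = _result(loglik=-5800.0)
    null.params = DHParameters(theta=[0.0], beta=[0.0], sigma=1.0, rho=0.2)
    out = lr_test(full, null)
    assert out["chi2"] == pytest.approx(200.0)
    assert pseudo_r2(_result()) == pytest.approx(1 - 5700.0 / 5800.0, abs=1e-9)
    assert pseudo_r2(_result()) == pytest.approx(0.017241, abs=1e-6)


def test_lr_identical_fits_give_zero():
    fit = _result(loglik=-100.0, loglik_null=-100.0)
    out = lr_test(fit, fit)
    assert out["chi2"] == 0.0
    assert pseudo_r2(fit) == 0.0


def test_lr_rejects_different_data():
    a = _result()
    b = _result()
    b.n_obs = 99
    with pytest.raises(ContractError):
        lr_test(a, b)


def test_informative_covariates_yield_larger_lr():
    """Strong covariate effects produce a large LR statistic with small p;
    the same design with pure-noise coefficients does not."""
    strong = binary_config(1500, seed=31, rho=0.0, theta=(0.5, -0.8), beta=(2.0, 1.0))
    noise = binary_config(1500, seed=31, rho=0.0, theta=(0.2, 0.0), beta=(2.0, 0.0))
    fits = {}
    for name, cfg in (("strong", strong), ("noise", noise)):
        dm = encode_design(simulate_households(cfg), cfg.design)
        fits[name] = fit_dh(dm, rho_mode="fixed_zero")
    assert fits["strong"].lr_chi2 > fits["noise"].lr_chi2
    assert fits["strong"].lr_p < 0.05
    assert fits["strong"].pseudo_r2 > 0


def test_participation_probability_closed_cases():
    params = DHParameters(theta=[0.0], beta=[1.0], sigma=1.0, rho=0.0)
    assert predict_participation(params, [[1.0]]) == pytest.approx(0.5)
    low = DHParameters(theta=[-40.0], beta=[1.0], sigma=1.0, rho=0.0)
    assert predict_expected_y(low, [1.0], [1.0]) == pytest.approx(0.0, abs=1e-12)


def test_expected_y_quadrature_matches_closed_form_linear_rho0():
    params = DHParameters(theta=[0.4], beta=[1.2], sigma=1.5, rho=0.0)
    q = predict_expected_y(params, [1.0], [1.0], method="quad")
    c = predict_expected_y(params, [1.0], [1.0], method="closed_form")
    b = 1.2 / 1.5
    manual = ndtr(0.4) * (1.2 * ndtr(b) + 1.5 * norm.pdf(b))
    assert q == pytest.approx(manual, abs=1e-8)
    assert c == pytest.approx(manual, abs=1e-12)


def test_expected_y_quadrature_matches_closed_form_exponential():
    params = DHParameters(theta=[0.3], beta=[1.0], sigma=0.8, rho=0.5, variant="exponential")
    q = predict_expected_y(params, [1.0], [1.0], method="quad")
    c = predict_expected_y(params, [1.0], [1.0], method="closed_form")
    assert q == pytest.approx(c, rel=1e-8)


def test_expected_y_dependent_matches_monte_carlo():
    """rho = 0.5 linear case against a 1e6-draw latent simulation."""
    params = DHParameters(theta=[0.4], beta=[1.0], sigma=1.5, rho=0.5)
    rng = np.random.default_rng(8)
    eps = rng.standard_normal(1_000_000)
    w = rng.standard_normal(1_000_000)
    v = 1.5 * (0.5 * eps + np.sqrt(1 - 0.25) * w)
    h = 1.0 + v
    y = np.where((0.4 + eps > 0) & (h > 0), h, 0.0)
    mc, mc_se = y.mean(), y.std() / 1000.0
    val = predict_expected_y(params, [1.0], [1.0], method="quad")
    assert abs(val - mc) < 3 * mc_se
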