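"""Maximum-likelihood fitting: recovery, nesting, starting-value fits."""

import numpy as np
import pytest

from dhurdle import (
    DesignMatrices,
    DoubleHurdle,
    encode_design,
    fit_dh,
    probit_fit,
    simulate_households,
    trunc_reg_fit,
)
from dhurdle.errors import DegenerateDataError

from conftest import binary_config, independence_test_config, recovery_config


@pytest.fixture(scope="module")
def recovery_fit():
    cfg = recovery_config(10_000, seed=5001)
    dm = encode_design(simulate_households(cfg), cfg.design)
    return cfg, fit_dh(dm, rho_mode="free", compute_null=False)


def test_estimates_within_three_se_of_truth(recovery_fit):
    cfg, fit = recovery_fit
    truth = cfg.true_params.as_array()
    assert fit.converged
    assert np.all(np.abs(fit.params.as_array() - truth) <= 3.0 * fit.se)


def test_free_rho_nests_fixed_zero(recovery_fit):
    cfg, fit_free = recovery_fit
    dm = encode_design(simulate_households(cfg), cfg.design)
    fit_fixed = fit_dh(dm, rho_mode="fixed_zero", compute_null=False)
    assert fit_free.loglik >= fit_fixed.loglik - 1e-6


def test_rho_recovered_at_the_null():
    cfg = independence_test_config(5000, seed=61, rho=0.0)
    dm = encode_design(simulate_households(cfg), cfg.design)
    fit = fit_dh(dm, rho_mode="free", compute_null=False)
    assert abs(fit.params.rho) <= 3.0 * fit.se[-1]


def test_vcov_symmetric_psd(recovery_fit):
    _, fit = recovery_fit
    assert np.allclose(fit.vcov, fit.vcov.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-10)


def test_probit_intercept_only_closed_form():
    d = np.tile([0.0, 1.0], 500)
    theta = probit_fit(np.ones((1000, 1)), d)
    assert theta[0] == pytest.approx(0.0, abs=1e-6)


def test_probit_separation_warns_and_stays_finite():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    z = np.column_stack([np.ones(200), x])
    d = (x > 0).astype(float)
    with pytest.warns(UserWarning, match="separation"):
        theta = probit_fit(z, d)
    assert np.all(np.isfinite(theta))


def test_truncated_regression_recovery():
    rng = np.random.default_rng(3)
    draws = rng.normal(1.0, 1.0, size=60_000)
    y = draws[draws > 0][:20_000]
    beta, sigma = trunc_reg_fit(np.ones((y.size, 1)), y)
    # 3 SEs of the truncated-normal MLE at n = 20,000 are ~0.04 here
    assert beta[0] == pytest.approx(1.0, abs=0.05)
    assert sigma == pytest.approx(1.0, abs=0.05)


def test_degenerate_outcomes_rejected():
    z = np.ones((50, 1))
    with pytest.raises(DegenerateDataError):
        fit_dh(DesignMatrices(z=z, X=z, y=np.zeros(50), z_names=["c"], x_names=["c"]))
    with pytest.raises(DegenerateDataError):
        fit_dh(DesignMatrices(z=z, X=z, y=np.ones(50), z_names=["c"], x_names=["c"]))


class TestDoubleHurdleEstimator:
    """Scikit-learn interface contract of the estimator class."""

    def _xy(self, n=3000, seed=17, rho=0.3):
        cfg = binary_config(n, seed=seed, rho=rho)
        table = simulate_households(cfg)
        x = (table["living_sector"] == "rural").to_numpy(float)[:, None]
        return x, table["oop_pharma"].to_numpy()

    def test_fit_predict_shapes_and_params(self):
        X, y = self._xy()
        m = DoubleHurdle(variant="linear", rho="fixed_zero").fit(X, y)
        assert m.theta_.shape == (2,) and m.beta_.shape == (2,)
        assert m.sigma_ > 0 and m.rho_ == 0.0
        pred = m.predict(X[:5])
        assert pred.shape == (5,) and np.all(pred >= 0)
        prob = m.predict_participation(X[:5])
        assert np.all((0 <= prob) & (prob <= 1))

    def test_clone_and_get_params_roundtrip(self):
        from sklearn.base import clone

        m = DoubleHurdle(variant="exponential", rho="fixed_zero", gtol=1e-7)
        m2 = clone(m)
        assert m2.get_params() == m.get_params()
        m2.set_params(variant="linear")
        assert m2.variant == "linear" and m.variant == "exponential"

    def test_separate_participation_design(self):
        X, y = self._xy()
        rng = np.random.default_rng(0)
        Z = np.column_stack([X, rng.normal(size=X.shape[0])])
        m = DoubleHurdle(rho="fixed_zero").fit(X, y, Z=Z)
        assert m.theta_.shape == (3,) and m.beta_.shape == (2,)

    def test_predict_monotone_in_participation_index(self):
        X, y = self._xy()
        m = DoubleHurdle(rho="fixed_zero").fit(X, y)
        # participation probability increases with z'theta by construction
        grid = np.array([[0.0], [1.0]])
        p = m.predict_participation(grid)
        sign = np.sign(m.theta_[1])
        assert sign * (p[1] - p[0]) >= 0
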