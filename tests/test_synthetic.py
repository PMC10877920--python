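"""Synthetic household generator: determinism, hurdle logic, marginal laws."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from dhurdle import (
    DesignSpec,
    DHParameters,
    SyntheticConfig,
    expected_zero_share,
    hies_like_config,
    simulate_households,
)
from dhurdle.design import CATEGORY_LEVELS
from dhurdle.errors import ConfigurationError, ParameterDomainError
from dhurdle.synthetic import RIALS_PER_USD, default_covariate_freqs

from conftest import binary_config


def _intercept_only_config(n, seed, theta0, beta0, sigma, rho=0.0, variant="linear"):
    design = DesignSpec(participation_terms=[], expenditure_terms=[])
    params = DHParameters(theta=[theta0], beta=[beta0], sigma=sigma, rho=rho, variant=variant)
    return SyntheticConfig(n_households=n, true_params=params, design=design, seed=seed)


def test_fixed_seed_is_bit_identical():
    cfg = binary_config(500, seed=9)
    t1 = simulate_households(cfg)
    t2 = simulate_households(cfg)
    pd.testing.assert_frame_equal(t1, t2)


def test_different_seeds_differ():
    a = simulate_households(binary_config(500, seed=1))
    b = simulate_households(binary_config(500, seed=2))
    assert not a["oop_pharma"].equals(b["oop_pharma"])


def test_hurdle_never_passed_gives_all_zeros():
    cfg = _intercept_only_config(1000, seed=3, theta0=-10.0, beta0=5.0, sigma=1.0)
    table = simulate_households(cfg)
    assert (table["oop_pharma"] == 0).all()


def test_hurdle_always_passed_tight_noise():
    cfg = _intercept_only_config(1000, seed=4, theta0=10.0, beta0=5.0, sigma=0.01)
    table = simulate_households(cfg)
    y = table["oop_pharma"].to_numpy()
    assert (y > 0).all()
    assert abs(y.mean() - 5.0) < 0.01


def test_zero_share_matches_closed_form_oracle():
    """Empirical zero share at n=1e5 agrees with the averaged
    1 - Phi2(z'theta, x'beta/sigma; rho) closed form within 3 MC SEs."""
    cfg = hies_like_config(n_households=100_000, seed=11)
    table = simulate_households(cfg)
    analytic = expected_zero_share(cfg, table)
    empirical = float((table["oop_pharma"] == 0).mean())
    mc_se = np.sqrt(analytic * (1 - analytic) / len(table))
    assert abs(empirical - analytic) < 3 * mc_se


def test_hies_config_calibrated_to_survey_zero_share():
    cfg = hies_like_config(n_households=1000, seed=0)
    assert expected_zero_share(cfg) == pytest.approx(2988 / 9381, abs=0.01)


def test_exponential_log_outcome_conditionally_normal():
    """At rho=0, log y among spenders is the plain normal error: KS at the
    true parameters must not reject at alpha = 0.01."""
    cfg = binary_config(10_000, seed=6, rho=0.0, variant="exponential",
                        beta=(1.0, 0.5), sigma=0.8)
    table = simulate_households(cfg)
    pos = table[table["oop_pharma"] > 0]
    mu = np.where(pos["living_sector"] == "rural", 1.5, 1.0)
    resid = (np.log(pos["oop_pharma"].to_numpy()) - mu) / 0.8
    assert kstest(resid, "norm").pvalue > 0.01


def test_exponential_positives_strictly_positive():
    cfg = binary_config(5000, seed=7, rho=0.4, variant="exponential", beta=(1.0, 0.5), sigma=0.8)
    y = simulate_households(cfg)["oop_pharma"].to_numpy()
    assert ((y == 0) | (y > 0)).all() and (y > 0).any() and (y == 0).any()


def test_category_frequencies_approach_targets():
    cfg = hies_like_config(n_households=50_000, seed=8)
    table = simulate_households(cfg)
    freqs = default_covariate_freqs()
    for var in ("head_gender", "education", "ownership"):
        for lev, p in freqs[var].items():
            emp = (table[var] == lev).mean()
            assert abs(emp - p) < 3 * np.sqrt(p * (1 - p) / len(table)) + 1e-9


def test_all_levels_from_closed_sets():
    table = simulate_households(hies_like_config(n_households=2000, seed=12))
    for var, levels in CATEGORY_LEVELS.items():
        assert set(table[var].unique()) <= set(levels)
    assert (table["oop_pharma"] >= 0).all()
    assert (table["n_children_under5"] >= 0).all()


def test_rial_emission_scales_monetary_columns():
    cfg_usd = binary_config(300, seed=5)
    cfg_rial = binary_config(300, seed=5)
    cfg_rial.emit_rials = True
    usd = simulate_households(cfg_usd)
    rial = simulate_households(cfg_rial)
    for col in ("income", "insurance_cost", "oop_pharma"):
        assert np.allclose(rial[col], usd[col] * RIALS_PER_USD)


def test_stream_splitting_isolates_variables():
    """Changing the income law must not perturb any other column."""
    a = binary_config(400, seed=13)
    b = binary_config(400, seed=13)
    b.income_law = ("gamma", {"shape": 2.0, "scale": 1500.0})
    ta, tb = simulate_households(a), simulate_households(b)
    assert not ta["income"].equals(tb["income"])
    for col in ta.columns:
        if col != "income":  # income is outside this design's hurdle indexes
            pd.testing.assert_series_equal(ta[col], tb[col])


def test_invalid_probability_vector_rejected():
    cfg = binary_config(100, seed=0)
    cfg.covariate_freqs["living_sector"] = {"urban": 0.7, "rural": 0.7}
    with pytest.raises(ConfigurationError):
        simulate_households(cfg)


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterDomainError):
        DHParameters(theta=[0.0], beta=[0.0], sigma=-1.0, rho=0.0)
    with pytest.raises(ParameterDomainError):
        DHParameters(theta=[0.0], beta=[0.0], sigma=1.0, rho=1.0)
    with pytest.raises(ConfigurationError):
        binary_config(0, seed=0).validate()


def test_config_roundtrip(tmp_path):
    from dhurdle.synthetic import load_config, save_config

    cfg = hies_like_config(n_households=123, seed=77)
    path = tmp_path / "cfg.yaml"
    save_config(cfg, path)
    back = load_config(path)
    pd.testing.assert_frame_equal(simulate_households(cfg), simulate_households(back))
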