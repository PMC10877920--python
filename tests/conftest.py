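"""Shared fixtures: small synthetic study designs used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from dhurdle import DesignSpec, DHParameters, SyntheticConfig
from dhurdle.synthetic import default_covariate_freqs


def _freqs_balanced_sector():
    freqs = default_covariate_freqs()
    freqs["living_sector"] = {"urban": 0.5, "rural": 0.5}
    return freqs


def binary_config(n, seed, rho=0.5, variant="linear", theta=(0.5, -0.8), beta=(2.0, 1.0), sigma=1.5):
    """One balanced binary covariate (living sector) in each hurdle."""
    design = DesignSpec(participation_terms=["living_sector"], expenditure_terms=["living_sector"])
    params = DHParameters(theta=np.asarray(theta, float), beta=np.asarray(beta, float),
                          sigma=sigma, rho=rho, variant=variant)
    return SyntheticConfig(n_households=n, true_params=params, design=design,
                           covariate_freqs=_freqs_balanced_sector(), seed=seed)


def recovery_config(n, seed, rho=0.5):
    """Exclusion-restriction design for clean identification of rho.

    Participation depends on income (continuous, per 10k USD), expenditure
    on the living sector only, so the inverse-Mills term varies
    independently of the expenditure covariates.
    """
    design = DesignSpec(participation_terms=["income"], expenditure_terms=["living_sector"],
                        scales={"income": 10000.0})
    params = DHParameters(theta=np.array([0.5, -0.8]), beta=np.array([2.0, 1.0]),
                          sigma=1.5, rho=rho, variant="linear")
    return SyntheticConfig(n_households=n, true_params=params, design=design,
                           covariate_freqs=_freqs_balanced_sector(), seed=seed)


def independence_test_config(n, seed, rho=0.0, variant="linear"):
    """Design for inference on rho near independence (income excluded from
    the expenditure equation; identification does not rest on the Mills
    nonlinearity alone)."""
    design = DesignSpec(participation_terms=["income", "living_sector"],
                        expenditure_terms=["living_sector"], scales={"income": 1000.0})
    params = DHParameters(theta=np.array([-0.3, 0.25, 0.6]), beta=np.array([1.5, 0.8]),
                          sigma=1.5, rho=rho, variant=variant)
    return SyntheticConfig(n_households=n, true_params=params, design=design,
                           covariate_freqs=_freqs_balanced_sector(), seed=seed)


@pytest.fixture(scope="session")
def small_table():
    """A 400-household linear-variant table with both zeros and positives."""
    from dhurdle import simulate_households

    cfg = binary_config(400, seed=42)
    return simulate_households(cfg), cfg
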