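"""Shared fixtures: small synthetic cohorts and a reusable fitted model."""

import logging
import warnings

import numpy as np
import pytest

import fertgp as fg

logging.getLogger("fertgp").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_truth():
    return fg.make_default_truth(cohort_size=2500)


@pytest.fixture(scope="session")
def obs_small(default_truth):
    """~15k woman-years from the default truth (6 census years)."""
    return fg.simulate_population(default_truth, seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale fit configuration for ~15k-row tables."""
    return fg.FitConfig(age_quantiles=30, ses_quantiles=5,
                        gamma_restarts=2, gp_restarts=5, seed=7)


@pytest.fixture(scope="session")
def fitted_model(obs_small, small_config):
    return fg.fit_fertility_model(obs_small, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
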