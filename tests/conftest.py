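"""Shared fixtures: small detection datasets and one full-scale fit.

The full-scale environmental-model fit is expensive (minutes), so it is
computed once per session and shared between the parameter-recovery
unit test and the acceptance checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beeshift.model import MultiSpeciesOccupancyModel
from beeshift.simulate import SimConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="ArviZ is undergoing", category=FutureWarning)


#: study-condition generator settings for the main recovery experiment
RECOVERY_CONFIG = dict(
    n_species=20,
    n_sites=150,
    mu_psi_temp=-1.5,
    psi_temp2=-0.3,
    mu_psi_precip=0.05,
    mu_psi_floral=-0.15,
    sigma_psi_temp=0.5,
    sigma_psi_precip=0.5,
    sigma_psi_floral=0.5,
)


@pytest.fixture(scope="session")
def recovery_fit():
    """Environmental-model fit on a full-scale synthetic community.

    Returns (results, truth); ground-truth community hyperparameters are
    those of RECOVERY_CONFIG.
    """
    config = SimConfig(**RECOVERY_CONFIG)
    data, cov, truth = generate_dataset(config, seed=1)
    model = MultiSpeciesOccupancyModel(data, cov, kind="environmental")
    results = model.fit(
        n_chains=2, n_warmup=400, n_draws=400, seed=1, max_treedepth=9
    )
    return results, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_dataset():
    """Small but non-trivial simulated dataset for structural tests."""
    config = SimConfig(n_species=4, n_sites=12, seed=5)
    return generate_dataset(config, seed=5)
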