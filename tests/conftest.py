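"""Shared fixtures.

The expensive MCMC fits are session-scoped so the convergence,
validation and summary tests all share one fit of the study-like
fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

from seabirdipm import (
    MCMCConfig,
    ModelOptions,
    StateSpaceModel,
    generate_dataset,
    run_mcmc,
    scenario_paper_like,
)


@pytest.fixture(scope="session")
def paperlike_dataset():
    return generate_dataset(scenario_paper_like())


@pytest.fixture(scope="session")
def paperlike_model(paperlike_dataset):
    cfg = paperlike_dataset.config
    return StateSpaceModel(
        paperlike_dataset.to_model_data(),
        options=ModelOptions(c_scaler=cfg.c_scaler),
    )


@pytest.fixture(scope="session")
def paperlike_fit(paperlike_model):
    """Desk-scale fit of the study-like fixture (3 chains)."""
    mc = MCMCConfig(chains=3, iterations=40_000, thin=10, burn_in=2_000, seed=1)
    return run_mcmc(paperlike_model, mc)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
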