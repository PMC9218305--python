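"""Shared fixtures: one moderate synthetic dataset and its fitted model.

The fitted model is session-scoped because the Gibbs sampler is the
expensive step; shrinkage, estimation and policy tests all reuse it.
"""

from __future__ import annotations

import pandas as pd
import pytest
from scipy.special import logit

import smallarea as sa

TRUTH = dict(sigma2_state=0.18, sigma2_district=0.07, sigma2_cluster=0.28)
BETA0 = float(logit(0.176))


@pytest.fixture(scope="session")
def toy_hierarchy() -> pd.DataFrame:
    return sa.generate_hierarchy(2, 2, 2, 2, seed=1)


@pytest.fixture(scope="session")
def sim_records() -> pd.DataFrame:
    """~6k children over 10 states with known latent variance components."""
    hier = sa.generate_hierarchy(10, (4, 6), (4, 6), 22, seed=42)
    truth = sa.SimulationTruth(beta0=BETA0, seed=43, **TRUTH)
    return sa.simulate_outcomes(hier, truth)


@pytest.fixture(scope="session")
def sim_sample(sim_records) -> pd.DataFrame:
    sample, _ = sa.build_analysis_sample(sa.add_outcomes(sim_records), "lbw")
    return sample


@pytest.fixture(scope="session")
def fitted_model(sim_sample) -> sa.ModelFit:
    spec = sa.ModelSpec(n_levels=4, burn_in=300, monitored=2000, seed=7)
    return sa.summarize_chain(sa.fit_mcmc(sim_sample, spec))
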