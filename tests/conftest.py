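"""Shared fixtures: small synthetic surveys and the parameter-recovery scenario."""

from __future__ import annotations

import numpy as np
import pytest

from snakerisk import SyntheticConfig, generate_survey
from snakerisk.synthetic import DEFAULT_SURFACES


def recovery_config(seed: int, **overrides) -> SyntheticConfig:
    """The simulation-study scenario: 80 clusters x 25 households (n = 2,000)
    on a 250 x 80 km strip, field SD 1 and range 30 km, fitted-model effect
    sizes, ~25% positive outcomes (enough cases for the hyperparameters to
    be identifiable at this n), latent field at cluster centres."""
    surfaces = dict(DEFAULT_SURFACES)
    defaults = dict(
        region_extent=(250.0, 80.0),
        n_clusters=80,
        households_per_cluster=25,
        outcome_prevalence_target=0.25,
        covariate_field_params=surfaces,
        n_water_features=15,
        dense_limit=1,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


#: hyperprior bounds for the range used throughout the simulation studies
#: (fixed a priori, the analogue of setting the range prior from pilot runs)
RHO_PRIOR = (3.0, 300.0)


@pytest.fixture(scope="session")
def small_survey():
    """A small but complete survey (30 clusters x 20 households)."""
    cfg = recovery_config(seed=42, n_clusters=30, households_per_cluster=20)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
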