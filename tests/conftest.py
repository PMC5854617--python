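import numpy as np
import pandas as pd
import pytest

from cascade_sdm import SurveyDataset, normalize_environment
from cascade_sdm.network import TrainConfig
from cascade_sdm.simulate import (
    CommunitySimConfig,
    EnvVarSim,
    SpeciesSim,
    simulate_community,
)


@pytest.fixture
def tiny_survey() -> SurveyDataset:
    """Hand-built 6-site, 3-species, 2-variable survey."""
    sites = [f"s{i}" for i in range(6)]
    occ = pd.DataFrame(
        {
            "perch": [1, 0, 1, 0, 1, 0],
            "pike": [1, 1, 0, 0, 1, 0],
            "tench": [0, 0, 0, 1, 0, 1],
        },
        index=sites,
    )
    env = pd.DataFrame(
        {"depth": [0.2, 0.4, 0.6, 0.8, 1.0, 1.2], "ph": [6.0, 6.5, 7.0, 7.5, 8.0, 8.5]},
        index=sites,
    )
    return SurveyDataset(occ, env)


def small_sim_config(seed: int = 0, n_sites: int = 160) -> CommunitySimConfig:
    """A compact two-latent community used across the model-level tests.

    The target tracks observed latent 0 plus a hidden latent 2 that no
    environmental variable measures; a strong co-predictor tracks both
    sharply; a noise species tracks nothing.  Six environmental variables
    observe latents 0 and 1 weakly.
    """
    env = [
        EnvVarSim("e0", (0.8, 0.1, 0.0), 0.8, 0.0, 10.0),
        EnvVarSim("e1", (0.7, -0.2, 0.0), 0.8, 0.0, 100.0),
        EnvVarSim("e2", (-0.6, 0.3, 0.0), 0.8, 0.0, 1.0),
        EnvVarSim("e3", (0.5, 0.5, 0.0), 0.9, 1.0, 5.0),
        EnvVarSim("e4", (-0.2, 0.8, 0.0), 0.9, 0.0, 50.0),
        EnvVarSim("e5", (0.1, -0.7, 0.0), 0.9, 0.0, 8.0),
    ]
    species = [
        SpeciesSim("target", (1.6, 0.0, 1.4), intercept=-0.5),
        SpeciesSim("strong_co", (3.5, 0.0, 2.0), intercept=0.0),
        SpeciesSim("weak_co", (0.8, 0.6, 0.3), intercept=-0.3),
        SpeciesSim("noise_sp", (0.0, 0.0, 0.0), intercept=-0.5),
    ]
    return CommunitySimConfig(
        n_sites=n_sites,
        latent_dims=3,
        env=env,
        species=species,
        target_name="target",
        copredictor_names=("strong_co",),
        seed=seed,
        truth_correlations=False,
    )


@pytest.fixture(scope="session")
def small_survey() -> SurveyDataset:
    """Normalized 160-site simulated survey (session-cached; do not mutate)."""
    data, _ = simulate_community(small_sim_config(seed=7))
    return normalize_environment(data)


@pytest.fixture(scope="session")
def quick_config() -> TrainConfig:
    """Small, fast, seeded training configuration for model-level tests."""
    return TrainConfig(
        n_hidden=3, weight_decay=1e-3, max_iterations=150, tolerance=1e-6, restarts=2
    )
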