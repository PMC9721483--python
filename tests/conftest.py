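import numpy as np
import pytest

from rloed import (
    ChemostatOEDEnv,
    EpisodeConfig,
    NOMINAL_PARAMETERS,
    NoiseModel,
    ObservationSpec,
    SolverConfig,
)


@pytest.fixture(scope="session")
def nominal():
    return NOMINAL_PARAMETERS


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture()
def env():
    return ChemostatOEDEnv(obs_spec=ObservationSpec("Ia"))


@pytest.fixture(scope="session")
def short_episode():
    """Two-interval protocol for cheap designer mechanics tests."""
    return EpisodeConfig(n_steps=2)


def random_policy(seed=0, bounds=(0.01, 1.0)):
    rng = np.random.default_rng(seed)
    return lambda o, tau: rng.uniform(bounds[0], bounds[1], 2)
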