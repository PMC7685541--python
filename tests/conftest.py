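import numpy as np
import pytest

from forestpower import SimulationConfig, simulate_normal, simulate_uniform
from forestpower.rf import ForestSpec


@pytest.fixture(scope="session")
def uniform_small():
    """Uniform-latent benchmark: 120 samples, 60 correlated + 10 noise."""
    return simulate_uniform(SimulationConfig(n_obs=120, p_total=70, seed=101))


@pytest.fixture(scope="session")
def normal_small():
    return simulate_normal(
        SimulationConfig(n_obs=120, p_total=70,
                         base_distribution="standard_normal", seed=102))


@pytest.fixture(scope="session")
def noise_data():
    """Pure-noise regression problem: features carry no outcome signal."""
    rng = np.random.default_rng(7)
    X = rng.uniform(size=(60, 30))
    y = rng.standard_normal(60)
    return X, y


def small_spec(task="regression", n_trees=60, seed=0, **kw):
    return ForestSpec(task=task, n_trees=n_trees, seed=seed, **kw)


@pytest.fixture
def spec_factory():
    return small_spec
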