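import numpy as np
import pytest

from hardvessel.synthfundus import SimConfig, desk_config, make_dataset


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    """A 64×64 configuration small enough for brute-force oracles."""
    return desk_config(seed=11, size=64, n_trees=2, max_depth=3)


@pytest.fixture(scope="session")
def tiny_samples(tiny_sim_config):
    return make_dataset(tiny_sim_config, 3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
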