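import numpy as np
import pytest

from woodpool.config import SimulationConfig
from woodpool.synthetic import (
    generate_affinities,
    generate_communities,
    generate_landscape,
)


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down landscape (3 stands per type, reduced species pools)
    keeping the default survey design and intensity structure."""
    cfg = SimulationConfig(
        n_stands_by_type={"clearcut": 3, "young": 3, "old": 3, "unmanaged": 3},
        n_species_by_taxon={"fungi": 25, "lichens": 12, "beetles": 25},
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return small_sim_config(seed=42)


@pytest.fixture(scope="session")
def landscape(sim_config):
    return generate_landscape(sim_config)


@pytest.fixture(scope="session")
def affinities(sim_config):
    return generate_affinities(sim_config)


@pytest.fixture(scope="session")
def communities(landscape, affinities, sim_config):
    _, items = landscape
    return generate_communities(items, affinities, sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
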