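import numpy as np
import pytest

from zmapsoz.synthetic import (
    SimulationConfig,
    make_parcellation_pair,
    make_surface_pair,
    simulate_volume_scene,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def surface_pair(sim_config):
    return make_surface_pair(sim_config.mesh_subdivisions, sim_config.seed)


@pytest.fixture(scope="session")
def parcellation(surface_pair, sim_config):
    return make_parcellation_pair(
        surface_pair, sim_config.n_regions_per_hemisphere, sim_config.seed
    )


@pytest.fixture(scope="session")
def scene(sim_config, surface_pair, parcellation):
    return simulate_volume_scene(sim_config, pair=surface_pair, parcellation=parcellation)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
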