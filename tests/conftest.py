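import numpy as np
import pytest

import shotgun_conn as sc


@pytest.fixture(scope="session")
def small_net():
    """A 20-neuron default network (Dale's law, ~3 Hz regime)."""
    return sc.generate_network(sc.NetworkGenConfig(N=20, seed=11))


@pytest.fixture(scope="session")
def small_raster(small_net):
    """2e5 bins of GLM activity from the 20-neuron network."""
    return sc.simulate_glm(small_net, 200_000, seed=12)


@pytest.fixture(scope="session")
def small_moments(small_raster):
    return sc.exact_moments(small_raster)


@pytest.fixture(scope="session")
def fixtures_bundle():
    return sc.make_fixtures(seed=0)
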