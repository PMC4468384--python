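import numpy as np
import pytest

from obpc.network import NetworkConfig, build_network


@pytest.fixture(scope="session")
def cfg() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def net(cfg):
    """One default network, shared read-only across tests."""
    return build_network(cfg, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
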