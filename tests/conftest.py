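import numpy as np
import pytest

from fcmgrn import GeneratorConfig, make_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark():
    """5-node, 40%-density ground truth with a (5, 4) sequence set."""
    config = GeneratorConfig(
        n_nodes=5, edge_density=0.4, n_sequences=5, n_time=4, seed=7
    )
    return make_benchmark(config)


@pytest.fixture(scope="session")
def medium_benchmark():
    """10-node, 20%-density ground truth with a (40, 10) sequence set."""
    config = GeneratorConfig(
        n_nodes=10, edge_density=0.2, n_sequences=40, n_time=10, seed=3
    )
    return make_benchmark(config)
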