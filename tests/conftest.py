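import logging

import numpy as np
import pytest

from anogva import GraphPopulation, erdos_renyi


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # degenerate-bandwidth warnings are expected in small simulations
    logging.getLogger("anogva").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def er_populations():
    """Three small ER populations drawn from one process (null data)."""
    def make(seed, n_graphs=8, n=30, p=0.25):
        rng = np.random.default_rng(seed)
        return [
            GraphPopulation(f"g{i + 1}",
                            [erdos_renyi(n, p, rng) for _ in range(n_graphs)])
            for i in range(3)
        ]
    return make
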