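import numpy as np
import pandas as pd
import pytest

from phytonet import (
    ReplicateTable,
    default_network,
    equicorrelated_scenario,
    simulate_correlated,
)


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture
def equicorrelated_table():
    """Factory: equicorrelated MVN table with the default network's columns."""

    def make(rho: float, n: int, seed: int = 0) -> ReplicateTable:
        names = default_network().variable_names
        return simulate_correlated(
            equicorrelated_scenario(len(names), rho, n, seed=seed, variables=names)
        )

    return make


@pytest.fixture
def small_table():
    """Seven-replicate table with a hand-checkable structure."""
    rng = np.random.default_rng(5)
    names = default_network().variable_names
    data = pd.DataFrame(rng.normal(size=(7, len(names))), columns=list(names))
    return ReplicateTable("sp", "tr", data)
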