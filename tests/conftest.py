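import numpy as np
import pytest

from mbcdeg.containers import CountMatrix
from mbcdeg.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def two_group_config():
    """Small two-group simulation used across tests."""
    return SimulationConfig(
        n_genes=2000,
        replicates=(3, 3),
        p_deg=0.25,
        deg_assign=(0.5, 0.5),
        fc_spec=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_group_data(two_group_config):
    return simulate_counts(two_group_config)


@pytest.fixture
def toy_counts():
    """A tiny deterministic 5-gene x 4-sample matrix (two groups)."""
    counts = np.array(
        [
            [10, 12, 40, 44],
            [100, 90, 95, 105],
            [0, 1, 2, 0],
            [50, 55, 48, 52],
            [5, 8, 6, 7],
        ]
    )
    return CountMatrix(
        counts,
        [f"g{i}" for i in range(1, 6)],
        ["s1", "s2", "s3", "s4"],
        [0, 0, 1, 1],
    )
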