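import logging

import numpy as np
import pytest

from planact import simulate

logging.getLogger("planact").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    # fresh per test: results do not depend on test execution order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_epochs():
    """One participant, a few trials per cell, full montage."""
    cfg = simulate.SimulationConfig(n_participants=1, trials_per_cell=10, seed=7)
    sets, _ = simulate.simulate_dataset(cfg)
    return sets[0]


@pytest.fixture(scope="session")
def small_dataset():
    """Four participants, default effect structure, reduced trials."""
    cfg = simulate.SimulationConfig(n_participants=4, trials_per_cell=12, seed=11)
    return simulate.simulate_dataset(cfg)
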