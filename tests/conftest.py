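import logging

import numpy as np
import pytest

from rapoport.synthetic import SimulationConfig, simulate_world
from rapoport.synthetic import simulate_tree

logging.getLogger("rapoport").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tree64():
    """Fixed 64-tip Yule tree shared by the signal-calibration tests."""
    return simulate_tree(64, seed=20240)


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world (40 species on a 20×30 lattice)."""
    cfg = SimulationConfig(
        n_species=40, domain_extent=(0.0, 0.0, 1000.0, 1500.0), seed=5
    )
    return cfg, simulate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
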