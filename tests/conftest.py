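import numpy as np
import pytest

from snowsel.grid import Grid
from snowsel.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A fast, reduced-extent landscape used by most integration tests."""
    return SyntheticConfig(seed=7, extent=300, n_animals=2, n_steps=300)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    return generate_bundle(small_cfg)


@pytest.fixture
def flat_grid():
    def make(value=0.0, n=12, cell=1.0):
        return Grid(np.full((n, n), float(value)), origin_x=0.0, origin_y=n * cell, cell=cell)

    return make
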