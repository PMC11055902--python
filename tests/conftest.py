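import numpy as np
import pytest

from fbqp import AlphaGrid, reference_scenario


@pytest.fixture(scope="session")
def grid():
    return AlphaGrid.uniform(101)


@pytest.fixture(scope="session")
def coarse_grid():
    return AlphaGrid.uniform(11)


@pytest.fixture(scope="session")
def example(grid):
    """The reference parabolic scenario on the default 101-level grid."""
    return reference_scenario(grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240427)
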