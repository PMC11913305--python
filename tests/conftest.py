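import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ratioimpute import draw_population


@pytest.fixture(scope="session")
def population():
    """The standard 100,000-unit population at sigma^2 = 1, fixed seed."""
    return draw_population(seed=7)


@pytest.fixture(scope="session")
def small_population():
    """A small population for cheap sampling tests."""
    return draw_population(size=2000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
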