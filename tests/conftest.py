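import numpy as np
import pytest
from hypothesis import settings

from ramancd import Spectrum, make_grid

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def amide_grid():
    """The amide I window slice of the acquisition grid."""
    return make_grid(1550.0, 1750.0, 1.9285)


@pytest.fixture
def single_gaussian(amide_grid):
    """Noise-free lone band: a=5, c=1650, sigma=8."""
    y = 5.0 * np.exp(-((amide_grid - 1650.0) ** 2) / (2 * 8.0**2))
    return Spectrum(amide_grid, y, subject_id="unit")
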