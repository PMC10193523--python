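import numpy as np
import pytest

from cmumd import LJParams, RegionSpec, initialize_system


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def planar_region():
    """CR [4, 8] with FR centred at 10 (CR below the FR, direction -1)."""
    return RegionSpec(cr_lo=4.0, cr_hi=8.0, fr_center=10.0, fr_width=0.5)


@pytest.fixture
def small_fluid():
    return initialize_system(30, 70, [6.0, 6.0, 6.0], temperature=0.85, seed=7)


@pytest.fixture
def lj():
    return LJParams()
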