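import numpy as np
import pytest

from qttcme.models import birth_death, futile_cycle, toggle_switch


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bd1_small():
    """Single birth-death species on 8 states."""
    return birth_death(1, 8)


@pytest.fixture(scope="session")
def toggle_tiny():
    """Toggle switch on a 16 x 16 window (dense-checkable)."""
    return toggle_switch(n=16)


@pytest.fixture(scope="session")
def futile_tiny():
    """Futile cycle with 3 substrate copies: 4*4*16 = 256 states."""
    return futile_cycle(s_total=3)
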