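import numpy as np
import pytest

from msmdock import ScreenSpec, ToyProteinSpec, make_synthetic_screen, make_toy_protein


@pytest.fixture(scope="session")
def toy_pair():
    """Closed (collapsed cavity) and open (hollow shell) toy conformations."""
    return make_toy_protein(ToyProteinSpec())


@pytest.fixture(scope="session")
def screen():
    """The default synthetic screen fixture (9 compounds, 20 states, 25% open)."""
    return make_synthetic_screen(ScreenSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
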