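import numpy as np
import pytest

from crystfold import ThermoConstants
from crystfold.synthetic import TABLE_FOUR_STATE, TABLE_TWO_STATE


@pytest.fixture(scope="session")
def thermo() -> ThermoConstants:
    return ThermoConstants()


@pytest.fixture(scope="session")
def two_state_truth():
    """Published two-state truth for the urea tetramer->monomer transition."""
    return TABLE_TWO_STATE


@pytest.fixture(scope="session")
def four_state_truth():
    """Published four-state truth for GdmCl unfolding of the monomer."""
    return TABLE_FOUR_STATE


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160105)
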