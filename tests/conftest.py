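import numpy as np
import pytest

from gabaclamp.conductance import default_template_library
from gabaclamp.membrane_sim import RCParams

#: Study capacitance grid for the in-silico analysis (pF).
C_GRID = (8.0, 10.0, 12.0, 14.0, 16.0)


@pytest.fixture(scope="session")
def library():
    return default_template_library()


@pytest.fixture()
def rc():
    return RCParams(r_mohm=737.0, c_pf=12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
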