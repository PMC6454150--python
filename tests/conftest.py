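import numpy as np
import pytest

from nvulnaa.forcing import PLASMA_CL_UM, PLASMA_PHE_UM, PlasmaForcing
from nvulnaa.params import nominal_parameters
from nvulnaa.simulate import solve_steady_state


@pytest.fixture(scope="session")
def params():
    return nominal_parameters()


@pytest.fixture(scope="session")
def physiologic_forcing():
    return PlasmaForcing(phe_ss=PLASMA_PHE_UM, cl_ss=PLASMA_CL_UM, cf=0.0)


@pytest.fixture(scope="session")
def baseline(params, physiologic_forcing):
    """The model's own physiologic steady state (plasma 77/739 uM)."""
    return solve_steady_state(physiologic_forcing, params)


@pytest.fixture(scope="session")
def steady_states_vs_plasma_phe(params):
    """Steady states over the plasma Phe levels spanned by the study."""
    out = {}
    for phe in (77.0, 300.0, 800.0, 1600.0):
        f = PlasmaForcing(phe_ss=phe, cf=0.0)
        out[phe] = solve_steady_state(f, params)
    return out
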