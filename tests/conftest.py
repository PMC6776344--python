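import numpy as np
import pytest

from donnanflux.parameters import (BathComposition, IonSpecies,
                                   get_parameter_set)

#: measured/derived parameter sets keyed by FCD (mM):
#: (c_Na,p, c_Cl,p, dmu_Na, dmu_Cl, dmu_Gd, D_Gd,poly, Gd partition ratio)
PARAM_TABLE = {
    -73: (202, 129, -0.0958, -0.0512, -0.2050, 4.1e-10, 0.82),
    -92: (216, 124, -0.1105, -0.0635, -0.2600, 3.9e-10, 0.78),
    -108: (223, 115, -0.1211, -0.0099, -0.2500, 3.7e-10, 0.74),
}

SET_NAMES = {-73: "fcd-73", -92: "fcd-92", -108: "fcd-108"}


@pytest.fixture(scope="session")
def pset_108():
    return get_parameter_set("fcd-108")


@pytest.fixture
def ideal_bath():
    return BathComposition(c_nacl_salt=150.0, fcd=0.0)


def make_ion(name="X", valence=-1, d=1e-9, dmu=0.0):
    return IonSpecies(name, valence, d, d, d, dmu)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
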