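import warnings

import pytest

from acrykin.chassis import ChassisSpec, make_chassis, make_continuous
from acrykin.dynamics import find_steady_state
from acrykin.pathways import VariantSpec, build_variant

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def glucose_chassis():
    model, twin = make_chassis(ChassisSpec())
    return model


@pytest.fixture(scope="session")
def glucose_twin():
    model, twin = make_chassis(ChassisSpec())
    return twin


@pytest.fixture(scope="session")
def glu_gly_aa(glucose_chassis):
    """Glucose-fed, glycerol-route, acrylic-acid-producing variant."""
    return build_variant(glucose_chassis, VariantSpec("glucose", "glycerol", "AA"))


@pytest.fixture(scope="session")
def glu_mcoa_aa(glucose_chassis):
    return build_variant(glucose_chassis, VariantSpec("glucose", "malonyl_coa", "AA"))


@pytest.fixture(scope="session")
def chassis_steady_state(glucose_chassis):
    """Continuous-mode steady state of the bare glucose chassis."""
    cont = make_continuous(glucose_chassis)
    return cont, find_steady_state(cont)


@pytest.fixture(scope="session")
def glu_gly_steady(glu_gly_aa):
    cont = make_continuous(glu_gly_aa)
    return cont, find_steady_state(cont)
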