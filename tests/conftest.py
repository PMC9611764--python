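import numpy as np
import pytest

from ffr0d import (
    IdealizedFixtureSpec,
    SolverSettings,
    StructuredTreeParams,
    make_idealized,
)
from ffr0d.vessel_model import LumenProfile, StenosisSpec


@pytest.fixture(scope="session")
def tree_params() -> StructuredTreeParams:
    return StructuredTreeParams()


@pytest.fixture(scope="session")
def neglect_settings() -> SolverSettings:
    """Healthy-wall resistance ignored: the idealized-circuit regime."""
    return SolverSettings(neglect_healthy_resistance=True)


@pytest.fixture(scope="session")
def model1():
    return make_idealized(IdealizedFixtureSpec(variant="model1_no_branch"))


@pytest.fixture(scope="session")
def model2():
    return make_idealized(IdealizedFixtureSpec(variant="model2_upstream"))


@pytest.fixture(scope="session")
def model3():
    return make_idealized(IdealizedFixtureSpec(variant="model3_downstream"))


@pytest.fixture(scope="session")
def straight_profile() -> LumenProfile:
    """A 75 mm straight 3 mm vessel."""
    s = np.linspace(0.0, 75e-3, 151)
    return LumenProfile(s, np.full(s.size, 3e-3))


@pytest.fixture(scope="session")
def reference_stenosis() -> StenosisSpec:
    """The benchmark lesion: 10 mm long, area narrowed to 20 %."""
    return StenosisSpec(center_position=37.5e-3, length_L=10e-3, area_ratio=0.2)
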