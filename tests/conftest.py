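import pytest

from nrassess import (
    AssessmentConfig,
    assess,
    make_toy_world,
    validate_config,
)
from nrassess.core_model import Approach


@pytest.fixture(scope="session")
def world():
    return make_toy_world(seed=7)


@pytest.fixture(scope="session")
def layerset(world):
    return world.to_layerset()


@pytest.fixture
def cfg():
    return validate_config(AssessmentConfig())


@pytest.fixture(scope="session")
def run_count(world, layerset):
    return assess(layerset, dict(world.iucn), AssessmentConfig(approach=Approach.PC_A))


@pytest.fixture(scope="session")
def run_area(world, layerset):
    return assess(layerset, dict(world.iucn), AssessmentConfig(approach=Approach.PA_A))
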