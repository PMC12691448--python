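import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pdl1dyn import (BaseParams, EpsilonParams, StudyDesign, NoiseSpec,
                     generate_study, standard_arms)


@pytest.fixture(scope="session")
def bp():
    return BaseParams()


@pytest.fixture(scope="session")
def ep():
    return EpsilonParams()


@pytest.fixture(scope="session")
def emt6_arms():
    return standard_arms("EMT6")


@pytest.fixture(scope="session")
def arm_by_name(emt6_arms):
    return {a.name: a for a in emt6_arms}


@pytest.fixture(scope="session")
def noiseless_study(bp, ep):
    """Six-arm synthetic study at the default truth, no noise."""
    return generate_study(bp, ep, StudyDesign(), NoiseSpec(kind="none"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
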