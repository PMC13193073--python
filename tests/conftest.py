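import numpy as np
import pytest

from soil2bio.domain import rectangle_domain
from soil2bio.simulate import SimulationTruth, generate_cohort, generate_soil_field


@pytest.fixture(scope="session")
def domain():
    return rectangle_domain(2000.0, 2000.0)


@pytest.fixture(scope="session")
def truth():
    return SimulationTruth(seed=11)


@pytest.fixture(scope="session")
def soil(domain, truth):
    """One seeded soil-Pb field, skewed (5% outlier stratum)."""
    return generate_soil_field(domain, 400, truth)


@pytest.fixture(scope="session")
def cohort(domain):
    return generate_cohort(120, domain, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
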