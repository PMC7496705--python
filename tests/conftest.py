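import numpy as np
import pytest

from breathprint.simulate import (
    CohortDesign,
    SensorResponseModel,
    VOCSignature,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_design():
    """A compact but balance-feasible cohort: 22 cases / 20 controls, 2 devices."""
    return CohortDesign(
        n_cases_by_subsite={"oral": 8, "oropharynx": 8, "glottis": 6},
        n_controls=20,
        n_devices=2,
        min_per_class_per_device=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def default_signature():
    return VOCSignature()


@pytest.fixture(scope="session")
def default_response():
    return SensorResponseModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130501)
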