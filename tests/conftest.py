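import numpy as np
import pytest

from pipedesign import DesignOptions, PriorSpec, calibrate_grid
from pipedesign.scenarios import make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario1():
    return make_scenario("table1_s1")


@pytest.fixture(scope="session")
def scenario3():
    return make_scenario("table1_s3")


@pytest.fixture(scope="session")
def scenario4():
    return make_scenario("table1_s4")


@pytest.fixture(scope="session")
def scenario_a():
    return make_scenario("table2_A")


@pytest.fixture(scope="session")
def scenario_e():
    return make_scenario("table2_E")


@pytest.fixture(scope="session")
def weak_prior_study1(scenario1):
    """6x6 weak prior (strength 1/36) with medians at the scenario-1 truths."""
    spec = PriorSpec(medians=scenario1.truth, strength=1 / 36, theta=0.30)
    return calibrate_grid(spec)


@pytest.fixture(scope="session")
def weak_prior_study2(scenario_a):
    """4x4 weak prior (strength 1/16) with medians at the scenario-A truths."""
    spec = PriorSpec(medians=scenario_a.truth, strength=1 / 16, theta=0.20)
    return calibrate_grid(spec)


@pytest.fixture
def study1_options():
    return DesignOptions(theta=0.30, epsilon=0.8, cohort_size=2, n_cohorts=20)


@pytest.fixture
def study2_options():
    return DesignOptions(theta=0.20, epsilon=0.8, cohort_size=1, n_cohorts=50)
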