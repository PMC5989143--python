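import pytest
from hypothesis import HealthCheck, settings

from sepcea import DecisionTree, load_scenario

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tree():
    return DecisionTree()


@pytest.fixture(scope="session")
def baseline():
    return load_scenario("baseline")


@pytest.fixture(scope="session")
def scenario1():
    return load_scenario("scenario1")


@pytest.fixture(scope="session")
def scenario2():
    return load_scenario("scenario2")
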