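import pytest

from sixmwt.synth import WalkScenario, simulate_6mwt
from sixmwt.types import AnalysisConfig


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def standard_walk():
    """One noisy 2-minute walk at textbook-healthy gait, with ground truth."""
    scenario = WalkScenario(cadence=2.0, stride=0.6, test_duration=120.0, seed=12345)
    trace, truth = simulate_6mwt(scenario)
    return scenario, trace, truth
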