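import pytest

from sonokin import ExperimentConfig, make_echo_model, make_gait_profile, simulate_trial
from sonokin.experiment import run_experiment


@pytest.fixture(scope="session")
def default_result():
    """One full default synthetic experiment, shared across tests."""
    return run_experiment(ExperimentConfig(seed=1))


@pytest.fixture(scope="session")
def small_trial():
    """A 6 s normal-speed trial for stream/feature tests."""
    profile = make_gait_profile("normal", seed=11)
    echo = make_echo_model(seed=12)
    return simulate_trial(profile, echo, 6.0, "train1", seed=13)
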