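import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tiup

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig5_params() -> tiup.ModelParams:
    """Representative illustration parameters for the Weber-fraction curves."""
    return tiup.ModelParams(lambda_max=10000.0, K=100.0, n=1.0, sigma2=0.0625)


@pytest.fixture(scope="session")
def exp1_params() -> tiup.ModelParams:
    """Fitted population-code parameters for the duration-manipulation study."""
    return tiup.ModelParams(lambda_max=5.02e4, K=4.80e2, n=1.06, sigma2=8.58e-2)


@pytest.fixture(scope="session")
def exp2_params() -> tiup.ModelParams:
    """Fitted population-code parameters for the luminance-manipulation study."""
    return tiup.ModelParams(lambda_max=1.48e5, K=1.00e3, n=0.73, sigma2=5.73e-2)


@pytest.fixture(scope="session")
def exp1_trials(exp1_params):
    """Simulated Experiment 1 (20 participants, both tasks) at the fitted params."""
    return tiup.generate_experiment(exp1_params, 1, 20, np.random.default_rng(1))


@pytest.fixture(scope="session")
def exp2_trials(exp2_params):
    """Simulated Experiment 2 (20 participants, both tasks) at the fitted params."""
    return tiup.generate_experiment(exp2_params, 2, 20, np.random.default_rng(1))


@pytest.fixture(scope="session")
def exp1_thresholds(exp1_trials):
    return tiup.dl_from_runs(exp1_trials)


@pytest.fixture(scope="session")
def exp2_thresholds(exp2_trials):
    return tiup.dl_from_runs(exp2_trials)


@pytest.fixture(scope="session")
def exp2_fit(exp2_thresholds):
    """Point fit of the model to the simulated Experiment 2 thresholds."""
    return tiup.fit(exp2_thresholds, tiup.experiment_design(2))
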