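import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

MICRO_Y = np.array([-1.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def micro_setting():
    """The worked example: y=(-1,0,1), mu0=0, tau2_0=1, sigma2_A=1."""
    from paic import conjugate as cj

    return cj.NormalSetting(n=3, mu_0=0.0, tau2_0=1.0, sigma2_A=1.0)


@pytest.fixture(scope="session")
def micro_model(micro_setting):
    from paic import conjugate as cj

    return cj.make_model(micro_setting, MICRO_Y)


@pytest.fixture(scope="session")
def micro_draws(micro_setting):
    from paic import conjugate as cj

    rng = np.random.default_rng(2023)
    return cj.sample_exact_draws(micro_setting, MICRO_Y, 2000, rng, chains=2)


@pytest.fixture(scope="session")
def logit_experiment_200():
    """The 200-replication hierarchical-logit run shared by the
    acceptance and diagnostic tests (about a minute of compute)."""
    from paic.hierlogit import LogitConfig, run_experiment

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment(LogitConfig(replications=200, seed=1))
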