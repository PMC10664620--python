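import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctdose import DesignConfig, SamplerSettings, TruthSpec

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def acc_config():
    """Accelerated fully-sequential design used in the simulation study."""
    return DesignConfig(
        eta=3.0, gamma=0.9, x_min=5.0, x_max=80.0, delta=0.1, alpha=0.01,
        initial_dose=6.0, n_patients=18,
    )


@pytest.fixture(scope="session")
def std_config():
    """Standard (conservative) fully-sequential design."""
    return DesignConfig(
        eta=3.0, gamma=0.99, x_min=5.0, x_max=80.0, delta=0.1, alpha=0.001,
        initial_dose=6.0, n_patients=18,
    )


@pytest.fixture(scope="session")
def linear_truth():
    return TruthSpec(xi0=50.0, nu0=1.0, sigma0=0.1)


@pytest.fixture(scope="session")
def quick_settings():
    """Short chains for tests where MCMC precision is not the point."""
    return SamplerSettings(n_iterations=1200, n_burnin=300, seed=0)
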