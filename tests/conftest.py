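import pytest
from hypothesis import settings

from aapflux.simulate import SimConfig, simulate_activity

settings.register_profile("suite", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    """All noise off: the pipeline must return the configured truth."""
    return SimConfig(
        n_dates=4,
        date_sd=0.0,
        residual_sd=0.0,
        titration_noise_sd_ml=0.0,
        dpm_counting=False,
        community=None,
        seed=0,
    )


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    return simulate_activity(noise_free_config)


@pytest.fixture(scope="session")
def small_study():
    """A small stochastic study used by several integration tests."""
    return simulate_activity(SimConfig(n_dates=8, seed=42, community=None))
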