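import pytest

from bbbflux.pipeline import run_simulated_pipeline
from bbbflux.simulate import GeneratorConfig, generate_efflux_panel, simulate_study


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """One simulated study under the default (noisy) conditions."""
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def noise_free_config():
    return GeneratorConfig(seed=1).noise_free()


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    return simulate_study(noise_free_config)


@pytest.fixture(scope="session")
def pipeline_report(default_config):
    report, study = run_simulated_pipeline(default_config)
    return report


@pytest.fixture(scope="session")
def seed0_panel():
    return generate_efflux_panel(GeneratorConfig(seed=0))
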