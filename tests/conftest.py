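import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20120927)


@pytest.fixture
def small_config():
    """A small noisy screen with one planted regulator of each kind."""
    from iresscreen import PlantedRegulator, SimulationConfig

    return SimulationConfig(
        n_genes=20,
        seed=7,
        planted_regulators=(
            PlantedRegulator("GENE00003", 4.0),
            PlantedRegulator("GENE00007", 0.3, ires_specific=True),
            PlantedRegulator("GENE00011", 0.25, toxic=True),
        ),
    )


@pytest.fixture
def noiseless_config(small_config):
    from dataclasses import replace

    return replace(small_config, noise_cv=0.0, plate_effect_sd=0.0)
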