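import pytest

from sfmaps import SimulationConfig, make_catalog, simulate_subject


@pytest.fixture(scope="session")
def nsd_catalog():
    return make_catalog("nsd")


@pytest.fixture(scope="session")
def noiseless_subject(nsd_catalog):
    """1000-vertex NSD-like subject with zero trial noise (exact forward model)."""
    config = SimulationConfig(
        noise_sd_scale=0.0,
        noise_heterogeneity=0.0,
        negative_fraction=0.0,
        seed=7,
    )
    return simulate_subject(config, 0, nsd_catalog), config


@pytest.fixture(scope="session")
def noisy_subject(nsd_catalog):
    """1000-vertex subject at the default study conditions (noise SD = 0.5x mean)."""
    config = SimulationConfig(seed=3)
    return simulate_subject(config, 0, nsd_catalog), config
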