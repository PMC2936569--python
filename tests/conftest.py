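import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_data():
    """A small but complete simulated replicate shared across tests."""
    import tablup as tl

    cfg = tl.SimulationConfig(
        n_chromosomes=2,
        markers_per_chromosome=60,
        n_historical_generations=80,
        n_qtl=10,
    )
    return tl.simulate_dataset(cfg, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
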