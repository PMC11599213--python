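import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vehicle_channel():
    """One simulated 60 s baseline-condition channel with its ground truth."""
    from mea_ephys.synthetic_data import SimulationConfig, simulate_channel

    cfg = SimulationConfig(duration_s=60.0, seed=3)
    sig, truth = simulate_channel(
        cfg, "healthy/25mM/Veh", np.random.default_rng(3)
    )
    return cfg, sig, truth
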