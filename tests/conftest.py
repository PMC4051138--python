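import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A 50-kb simulated trio shared by module-level tests (cheap, deterministic)."""
    from aliensnp.simulate import SimulationConfig, evolve_trio

    cfg = SimulationConfig(
        seed=11,
        ancestor_length=50_000,
        n_planted_specific=30,
        n_planted_discordant=10,
        n_planted_flank_contaminated=6,
        coverage=15.0,
    )
    return evolve_trio(cfg)
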