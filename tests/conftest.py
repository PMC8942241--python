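import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def fullsib_data():
    """One deterministic full-sib polygenic replicate (10 families x 5 sibs)."""
    from qtlvar import simulate_fullsib_polygenic

    y, geno, kinship = simulate_fullsib_polygenic(10, 5, 0.15, seed=42)
    return y, geno, kinship
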