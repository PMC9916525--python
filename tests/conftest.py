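import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from ipscmine import SimConfig, simulate_study  # noqa: E402


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def study(default_config):
    """One full synthetic study shared by the suite (matrix, catalog,
    ppi, inducible, truth)."""
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def small_study():
    """A fast small-universe study for screens and io round-trips."""
    config = SimConfig(
        seed=5,
        n_genes=300,
        n_planted_up=30,
        n_planted_down=30,
        lib_size_baseline=150_000,
        lib_size_line=150_000,
        n_terms_per_level=8,
        term_size_range=(5, 20),
        n_inducible=10,
    )
    return config, simulate_study(config)
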