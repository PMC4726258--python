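import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_cross():
    """Small error-free, deeply covered cross: calls should equal truth."""
    from lowmap import SimConfig, simulate_cross

    cfg = SimConfig(n_chromosomes=2, scaffolds_per_chromosome=3,
                    scaffold_length_bp=60_000, blocks_per_scaffold=3,
                    block_span_bp=3_000, n_progeny=60, coverage=25.0,
                    miscall_rate=0.0, mismap_het_rate=0.0,
                    intercross_fraction=0.0, seed=42)
    return simulate_cross(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_cross):
    from lowmap import run_from_cross

    return run_from_cross(clean_cross, build_maps=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
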