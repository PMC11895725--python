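import pytest

from rxlink import SimConfig, generate_population
from rxlink.vocabulary import bundled_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return bundled_vocabulary()


@pytest.fixture(scope="session")
def small_population():
    """A modest default-config population shared by read-only tests."""
    return generate_population(SimConfig(n_patients=400, seed=42))


@pytest.fixture(scope="session")
def clean_population():
    """Noise-free population: no coverage misses, no decoys, everyone
    eligible — recovered quantities must equal the truth table exactly."""
    cfg = SimConfig(
        n_patients=400,
        seed=77,
        coverage_miss_rate=0.0,
        decoy_dispensing_rate=0.0,
        prior_use_rate=0.0,
        missed_capture_rate=0.0,
    )
    return generate_population(cfg)
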