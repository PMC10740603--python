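import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hostblock import (
    SimConfig,
    published_primer_set,
    simulate_refdb_with_truth,
)


@pytest.fixture(scope="session")
def published():
    """The published 18S V4 amplification pair and snail blocking primer."""
    return published_primer_set()


@pytest.fixture(scope="session")
def small_sim(published):
    """A small simulated database with truth (20 hosts, 20 non-targets)."""
    pair, _ = published
    cfg = SimConfig(seed=7, n_host=20, n_non_target=20, n_decoy=3)
    db, truth = simulate_refdb_with_truth(cfg, pair)
    return cfg, db, truth
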