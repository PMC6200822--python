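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
    return np.random.default_rng(20180)


def random_dna(rng, length):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), size=length)) \
        if isinstance(rng, (int, np.integer)) else \
        "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def small_genome_pair():
    """A compact simulated genome pair shared across alignment tests."""
    from npclkit.simulate import GenomeSimConfig, simulate_genome_pair

    cfg = GenomeSimConfig(
        n_exons=10, exon_len=(650, 1200), n_paralogs=2, n_deletions=2,
        intron_len=(150, 400), seed=11,
    )
    return simulate_genome_pair(cfg)
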