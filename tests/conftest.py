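import pytest

from genespace import synthetic as syn


@pytest.fixture(scope="session")
def small_genome():
    """100 kb genome, 30% gene, 50% repeat, 80% of repeat bp methylated."""
    return syn.simulate_genome(100_000, 0.3, 0.5, 0.8, seed=42)


@pytest.fixture(scope="session")
def enrichment_genome():
    """1 Mb genome whose hypomethylated fraction is 1/2.4."""
    hypo = 1 / 2.4
    return syn.simulate_genome(1_000_000, 0.25, 0.7, (1 - hypo) / 0.7, seed=7)
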