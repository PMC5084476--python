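import pytest

from grasskit import plastome as pl
from grasskit import synthetic as syn


@pytest.fixture(scope="session")
def small_plastome():
    """A 13.5 kb plastome with the quadripartite layout, plus its truth."""
    spec = syn.PlastomeSpec(lsc_len=8000, ssc_len=1500, ir_len=2000, seed=1)
    genome, partition = syn.generate_plastome(spec)
    return spec, genome, partition


@pytest.fixture(scope="session")
def small_reads(small_plastome):
    _, genome, _ = small_plastome
    return syn.shred_reads(
        genome, syn.ReadSimSpec(read_len=100, coverage=50.0, seed=2)
    )


@pytest.fixture(scope="session")
def small_read_index(small_reads):
    return pl.ReadKmerIndex(small_reads, k=20)
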