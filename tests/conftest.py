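import pytest

from mirforge.intervals import GenomicInterval
from mirforge.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """A small planted study reused across tests (50 loci, 2 clusters)."""
    cfg = SimulationConfig(seed=42, n_true_mirnas=50, n_decoys=25,
                           cluster_spec=[(3, 5000), (2, 8000)])
    return simulate_genome(cfg)


def iv(start, end, contig="ctg1", strand="+"):
    return GenomicInterval(contig, start, end, strand)
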