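import numpy as np
import pytest

from promap.core import GenomeSequence
from promap.simdata import SimConfig, random_seq, simulate_genome_pair

SMALL_LAYOUT = (
    ("chr1", 40_000, "chromosome"),
    ("chr2", 40_000, "chromosome"),
    ("GL000001", 8_000, "unplaced_scaffold"),
    ("GL000002", 8_000, "unplaced_scaffold"),
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_genome():
    """100-kb single-contig genome of random sequence."""
    g = GenomeSequence()
    g.add_contig("chr1", random_seq(np.random.default_rng(7), 100_000))
    return g


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated study (40 genes, no reads) shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_genes=40,
        cage_depth=0,
        rnaseq_depth=0,
        contig_layout=SMALL_LAYOUT,
    )
    return simulate_genome_pair(cfg)


@pytest.fixture(scope="session")
def small_sim_projected(small_sim):
    from promap.projection import project_promoters

    results = project_promoters(
        small_sim.source_promoters,
        small_sim.source_genome,
        small_sim.target_genome,
        small_sim.orthologs,
        small_sim.target_genes,
    )
    return small_sim, results
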