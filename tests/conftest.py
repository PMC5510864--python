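import numpy as np
import pytest

from retroseek import GenomicInterval
from retroseek import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_genome():
    """Two 120 kb chromosomes with one small gap each."""
    genome, gaps = sd.make_genome(
        seed=11, n_chrom=2, chrom_len=120_000, n_gaps_per_chrom=1, gap_len=1_000
    )
    return genome, gaps


@pytest.fixture(scope="session")
def toy_genes(toy_genome):
    genome, _ = toy_genome
    return sd.make_annotation(genome, n_genes=8, exons_per_gene=5, exon_len=250,
                              intron_len=300, seed=11, margin=5_000)


@pytest.fixture(scope="session")
def toy_gene_spans(toy_genes):
    return {
        g: GenomicInterval(e[0].chrom, min(x.start for x in e), max(x.end for x in e))
        for g, e in toy_genes.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
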