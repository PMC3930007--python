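import pytest
from hypothesis import settings

from adipomir.io_formats import GeneModel, GenomicInterval, MiRNAGene
from adipomir.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_qpcr,
)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

CANONICAL_SEED = 42


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def annotation_sim(sim_config):
    return simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def expression_sim(sim_config):
    return simulate_expression(sim_config)


@pytest.fixture(scope="session")
def qpcr_sim(sim_config):
    return simulate_qpcr(sim_config)


def make_mirna(gene_id, chrom, start, end, strand="+", name=None):
    return MiRNAGene(gene_id=gene_id, name=name or gene_id,
                     locus=GenomicInterval(chrom, start, end, strand))


def make_gene(gene_id, chrom, exon_bounds, strand="+"):
    """Single-transcript gene from a list of (start, end) exon bounds."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    locus = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return GeneModel(gene_id=gene_id, name=gene_id, locus=locus,
                     transcripts=[(f"{gene_id}.t1", exons)])


@pytest.fixture
def two_exon_gene():
    return make_gene("G1", "chr1", [(1000, 1200), (1500, 1800)])
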