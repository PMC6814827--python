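import numpy as np
import pytest

from clonotrace.io_formats import GeneModel, GenomicInterval, VariantCall
from clonotrace.synthetic import make_toy_genome


@pytest.fixture(scope="session")
def toy_world():
    """A 24-gene toy genome shared across tests (read-only)."""
    return make_toy_genome(n_genes=24, seed=101)


@pytest.fixture(scope="session")
def fusion_world():
    """A larger toy genome with extra close gene pairs for fusion decoys."""
    return make_toy_genome(n_genes=40, seed=202, n_close_pairs=4, genes_per_chrom=10)


@pytest.fixture
def mini_gene():
    """A hand-built single-exon gene with a known CDS: ATG CTT GGT AAA CCC.

    Positions 11..25 on chromosome 'mini', '+' strand.
    """
    cds = "ATGCTTGGTAAACCC"
    genome = {"mini": "T" * 10 + cds + "A" * 10}
    gene = GeneModel(
        gene_id="MINI1",
        gene_name="MINI1",
        chrom="mini",
        strand="+",
        exons=[GenomicInterval("mini", 11, 25)],
        cds=[GenomicInterval("mini", 11, 25)],
    )
    gene.validate()
    return genome, gene


def make_call(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    depth=50,
    alt_reads=20,
    gq=99,
    sample="S",
    vaf=None,
):
    return VariantCall(
        sample_id=sample,
        locus=GenomicInterval(chrom, pos, pos + len(ref) - 1),
        ref=ref,
        alt=alt,
        depth=depth,
        alt_reads=alt_reads,
        vaf=alt_reads / depth if vaf is None else vaf,
        genotype_quality=gq,
    )


def random_calls(n, seed, sample="S"):
    """Random well-formed VariantCalls spanning the filter boundaries."""
    rng = np.random.default_rng(seed)
    calls = []
    for i in range(n):
        depth = int(rng.integers(1, 200))
        alt = int(rng.integers(0, depth + 1))
        pos = 1000 + i
        calls.append(
            make_call(
                pos=pos,
                ref="ACGT"[pos % 4],  # ref deterministic per locus
                alt="TGCA"[int(rng.integers(4))],
                depth=depth,
                alt_reads=alt,
                gq=int(rng.integers(0, 100)),
                sample=sample,
            )
        )
    return calls
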