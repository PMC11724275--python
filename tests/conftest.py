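import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nacquant import (
    GeneModel,
    GenomeSequence,
    SimConfig,
    TranscriptModel,
    build_reference_index,
    collapse_umis,
    count_matrices,
    map_reads,
    simulate,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# k-mer size for pipeline-level tests: long enough that random toy genomes
# have essentially no repeated k-mers, short enough to keep indexing fast
K_PIPE = 21


def _locus_is_unambiguous(exon1, intron, exon2, k=7):
    """True when no intron-touching k-mer occurs in the spliced sequence and
    no junction-spanning k-mer occurs in the unspliced one.

    Small-k toy loci can otherwise produce sequence coincidences at the
    boundaries, which would make position-derived read labels unrecoverable
    from the read content itself.
    """
    from nacquant import canonical

    mature = exon1 + exon2
    nascent = exon1 + intron + exon2
    mature_kmers = {canonical(mature[i : i + k]) for i in range(len(mature) - k + 1)}
    nascent_kmers = {canonical(nascent[i : i + k]) for i in range(len(nascent) - k + 1)}
    i0, i1 = len(exon1), len(exon1) + len(intron)
    for p in range(len(nascent) - k + 1):
        if p < i1 and p + k > i0:  # window touches the intron
            if canonical(nascent[p : p + k]) in mature_kmers:
                return False
    j = len(exon1)
    for p in range(len(mature) - k + 1):
        if p < j < p + k:  # window spans the junction
            if canonical(mature[p : p + k]) in nascent_kmers:
                return False
    return True


@pytest.fixture(scope="session")
def toy_locus():
    """One plus-strand exon–intron–exon gene on a small contig, chosen so the
    boundaries carry no sequence coincidences at k >= 7."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        seg = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        spacer_l, exon1, intron, exon2, spacer_r = seg(40), seg(60), seg(50), seg(60), seg(40)
        if _locus_is_unambiguous(exon1, intron, exon2):
            break
    else:  # pragma: no cover
        raise AssertionError("no unambiguous toy locus found")
    genome = GenomeSequence("chr1", spacer_l + exon1 + intron + exon2 + spacer_r)
    exons = ((40, 100), (150, 210))
    gene = GeneModel("g1", "chr1", "+", (TranscriptModel("g1.t1", "g1", exons),))
    return {
        "genome": genome,
        "gene": gene,
        "exon1": exon1,
        "intron": intron,
        "exon2": exon2,
        "mature": exon1 + exon2,
        "nascent": exon1 + intron + exon2,
        "gene_span": (40, 210),
    }


def _run_pipeline(bundle, index, multimapping=False):
    records, stats = map_reads(
        index, [(r.barcode, r.umi, r.seq) for r in bundle.reads]
    )
    classified = collapse_umis(records, index)
    mats = count_matrices(
        classified, index, multimapping=multimapping, barcodes=bundle.barcodes
    )
    return mats, stats


@pytest.fixture(scope="session")
def run_pipeline():
    return _run_pipeline


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free benchmark: 50 cells x 20 genes x 200 UMIs, 60/30/10 mix."""
    return simulate(SimConfig(), seed=20260)


@pytest.fixture(scope="session")
def clean_nac_index(clean_sim):
    genome = {clean_sim.genome.name: clean_sim.genome}
    return build_reference_index(
        genome, clean_sim.genes, K_PIPE, mode="nac", dlist="genome"
    )


@pytest.fixture(scope="session")
def clean_counts(clean_sim, clean_nac_index):
    mats, stats = _run_pipeline(clean_sim, clean_nac_index)
    return {"matrices": mats, "stats": stats}


@pytest.fixture(scope="session")
def intergenic_sim():
    """Same scale, but 20% of reads are intergenic (gene-adjacent windows)."""
    return simulate(SimConfig(origin_mix=(0.5, 0.3, 0.2)), seed=777)
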