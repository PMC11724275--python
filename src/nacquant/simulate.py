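"""Synthetic single-cell RNA-seq data with position-derived ground truth.

The generator emulates the structure of a droplet single-cell experiment at
desk scale: a toy genome of multi-exon genes separated by intergenic spacers,
cells identified by synthetic barcodes from a fixed on-list, one read per UMI,
and molecules of three origins — mature (spliced), nascent (unspliced) and
intergenic.  Each read carries a position-derived expected classification:

* spans an exon–exon junction            → **M**
* covers any intronic base               → **N**
* fully within a single exon             → **A**
* any intergenic base (external origin)  → **filtered**

Truth count matrices tally UMIs by expected classification; intergenic reads
never enter them.  Sequencing errors are injected per base in three passes —
mismatches first, then deletions, then insertions — each pass independent and
order-preserving, at a default mismatch rate of 0.5%.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .count import CountMatrix, sum_matrices
from .errors import ConfigError
from .reference import GeneModel, GenomeSequence, TranscriptModel, write_gtf
from .cdbg import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe the desk-scale benchmark used throughout the test
    suite: 20 genes of 2–4 exons, 50 cells with 200 UMIs each, 91-bp reads,
    and a 60/30/10 mature/nascent/intergenic origin mix.  Error rates default
    to zero; the error benchmark uses a 0.5% mismatch rate.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (150, 350)
    intron_length: tuple[int, int] = (100, 300)
    intergenic_fraction: float = 0.25
    n_cells: int = 50
    umis_per_cell: int = 200
    genes_per_cell: Optional[int] = 8  # genes expressed per cell; None = all
    read_length: int = 91
    barcode_length: int = 16
    umi_length: int = 12
    origin_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)  # mature, nascent, intergenic
    mismatch_rate: float = 0.0
    del_rate: float = 0.0
    ins_rate: float = 0.0

    def __post_init__(self):
        if abs(sum(self.origin_mix) - 1.0) > 1e-9:
            raise ConfigError(f"origin_mix must sum to 1, got {self.origin_mix}")
        for r in (self.mismatch_rate, self.del_rate, self.ins_rate):
            if not (0.0 <= r < 1.0):
                raise ConfigError(f"error rates must be in [0,1), got {r}")
        if not (0.0 <= self.intergenic_fraction < 1.0):
            raise ConfigError("intergenic_fraction must be in [0,1)")
        if self.read_length < 1 or self.n_genes < 1 or self.n_cells < 1:
            raise ConfigError("n_genes, n_cells and read_length must be positive")
        if self.genes_per_cell is not None:
            if self.genes_per_cell < 1:
                raise ConfigError("genes_per_cell must be positive")
            # cells can express at most every gene
            self.genes_per_cell = min(self.genes_per_cell, self.n_genes)
        if self.exon_length[0] < 1 or self.intron_length[0] < 1:
            raise ConfigError("exon/intron lengths must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimRead:
    name: str
    barcode: str
    umi: str
    seq: str
    origin: str  # "mature" | "nascent" | "intergenic"
    expected_class: str  # "M" | "N" | "A" | "filtered"
    gene_id: Optional[str]


@dataclass
class TruthBundle:
    """Simulator output: reads plus ground-truth classification and matrices."""

    genome: GenomeSequence
    genes: list
    reads: list
    truth: dict  # status -> CountMatrix for N/M/A plus cell/nucleus/total
    barcodes: list
    config: SimConfig
    seed: int

    def write_fastq(self, r1_path, r2_path) -> None:
        with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
            for read in self.reads:
                tech = read.barcode + read.umi
                r1.write(f"@{read.name}\n{tech}\n+\n{'I' * len(tech)}\n")
                r2.write(f"@{read.name}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")

    def write_truth(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for status, mat in self.truth.items():
            mat.to_mtx(outdir / f"truth_{status}")
        with open(outdir / "truth_reads.tsv", "w") as fh:
            for r in self.reads:
                fh.write(
                    f"{r.name}\t{r.barcode}\t{r.umi}\t{r.origin}\t"
                    f"{r.expected_class}\t{r.gene_id or '.'}\n"
                )

    def write_reference(self, genome_path, gtf_path) -> None:
        with open(genome_path, "w") as fh:
            fh.write(f">{self.genome.name}\n{self.genome.seq}\n")
        write_gtf(self.genes, gtf_path)

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "n_reads": len(self.reads),
            "n_barcodes": len(self.barcodes),
            "genes": [g.gene_id for g in self.genes],
        }


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_reference(
    config: SimConfig, seed: int
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Toy genome: genes with exon/intron structure separated by intergenic
    spacers.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    gene_structs = []
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=max(n_exons - 1, 0)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gene_structs.append((exon_lens, intron_lens, strand))
    total_genic = sum(int(e.sum() + i.sum()) for e, i, _ in gene_structs)
    f = config.intergenic_fraction
    total_intergenic = int(round(total_genic * f / (1.0 - f))) if f > 0 else 0
    n_spacers = config.n_genes + 1
    if total_intergenic > 0:
        weights = rng.dirichlet(np.ones(n_spacers))
        spacer_lens = np.maximum((weights * total_intergenic).astype(int), 1)
    else:
        spacer_lens = np.zeros(n_spacers, dtype=int)

    pieces: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    width = max(2, len(str(config.n_genes)))
    for gi, (exon_lens, intron_lens, strand) in enumerate(gene_structs):
        spacer = int(spacer_lens[gi])
        pieces.append(_random_seq(rng, spacer))
        pos += spacer
        exons = []
        cursor = pos
        for ei, el in enumerate(exon_lens):
            exons.append((cursor, cursor + int(el)))
            cursor += int(el)
            if ei < len(intron_lens):
                cursor += int(intron_lens[ei])
        gene_len = cursor - pos
        pieces.append(_random_seq(rng, gene_len))
        gid = f"gene{gi + 1:0{width}d}"
        model = TranscriptModel(f"{gid}.t1", gid, tuple(exons))
        genes.append(GeneModel(gid, "chr1", strand, (model,)))
        pos = cursor
    pieces.append(_random_seq(rng, int(spacer_lens[-1])))
    genome = GenomeSequence("chr1", "".join(pieces))
    return genome, genes


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _encode_id(value: int, length: int) -> str:
    """Deterministic base-4 encoding of an integer as a DNA string."""
    chars = []
    for _ in range(length):
        chars.append(_BASE_STR[value % 4])
        value //= 4
    return "".join(reversed(chars))


def _mature_layout(gene: GeneModel) -> tuple[list[tuple[int, int]], list[int]]:
    """Exon intervals in transcript coordinates and junction positions."""
    t = gene.transcripts[0]
    exons = list(t.exons)
    if gene.strand == "-":
        exons = exons[::-1]
    junctions = []
    cursor = 0
    for s, e in exons[:-1]:
        cursor += e - s
        junctions.append(cursor)
    return exons, junctions


def _nascent_intron_mask(gene: GeneModel) -> np.ndarray:
    """Boolean mask over the nascent sequence: True where intronic."""
    t = gene.transcripts[0]
    span_s, span_e = gene.span
    mask = np.ones(span_e - span_s, dtype=bool)
    for s, e in t.exons:
        mask[s - span_s : e - span_s] = False
    if gene.strand == "-":
        mask = mask[::-1]
    return mask


def simulate_reads(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    config: SimConfig,
    seed: int,
) -> TruthBundle:
    """Draw reads from mature/nascent/intergenic molecules with ground truth.

    One read per UMI; UMIs are unique per cell by construction (no collision
    modelling).  Reads are drawn uniformly along their molecule and emitted in
    a uniformly random orientation (pseudoalignment is strand-agnostic).
    Sequencing errors, if configured, are injected afterwards in the
    mismatch → deletion → insertion order.
    """
    rng = np.random.default_rng(seed)
    L = config.read_length

    from .reference import extract_mature_transcripts, extract_nascent_transcripts

    mature = {r.gene_id: r.seq for r in extract_mature_transcripts({genome.name: genome}, genes)}
    nascent = {r.gene_id: r.seq for r in extract_nascent_transcripts({genome.name: genome}, genes)}
    layouts = {g.gene_id: _mature_layout(g) for g in genes}
    intron_masks = {g.gene_id: _nascent_intron_mask(g) for g in genes}

    mature_ok = [g.gene_id for g in genes if len(mature[g.gene_id]) >= L]
    nascent_ok = [g.gene_id for g in genes if len(nascent[g.gene_id]) >= L]
    mix = config.origin_mix
    if mix[0] > 0 and not mature_ok:
        raise ConfigError("no mature molecule is at least read_length long")
    if mix[1] > 0 and not nascent_ok:
        raise ConfigError("no nascent molecule is at least read_length long")

    # window start positions whose footprint covers >= 1 intergenic base
    genic = np.zeros(len(genome.seq), dtype=bool)
    for g in genes:
        s, e = g.span
        genic[s:e] = True
    intergenic_base = ~genic
    n_starts = len(genome.seq) - L + 1
    if mix[2] > 0:
        if n_starts < 1:
            raise ConfigError("genome shorter than read_length")
        prefix = np.concatenate([[0], np.cumsum(intergenic_base)])
        has_intergenic = (prefix[L:] - prefix[:-L]) > 0
        intergenic_starts = np.nonzero(has_intergenic)[0]
        if intergenic_starts.size == 0:
            raise ConfigError("no window overlaps intergenic sequence")
    else:
        intergenic_starts = np.empty(0, dtype=int)

    barcodes = [_encode_id(i, config.barcode_length) for i in range(config.n_cells)]
    reads: list[SimRead] = []
    truth_tally: dict[str, dict[tuple[str, str], float]] = {"N": {}, "M": {}, "A": {}}
    origins = ("mature", "nascent", "intergenic")
    all_gene_ids = [g.gene_id for g in genes]
    ridx = 0
    for ci, bc in enumerate(barcodes):
        # each cell expresses a random gene subset: real count matrices are
        # sparse, which is what makes FPR/FNR informative
        if config.genes_per_cell is not None:
            expressed = set(
                rng.choice(all_gene_ids, size=config.genes_per_cell, replace=False)
            )
        else:
            expressed = set(all_gene_ids)
        cell_mature = [g for g in mature_ok if g in expressed]
        cell_nascent = [g for g in nascent_ok if g in expressed]
        if mix[0] > 0 and not cell_mature:
            cell_mature = mature_ok
        if mix[1] > 0 and not cell_nascent:
            cell_nascent = nascent_ok
        for ui in range(config.umis_per_cell):
            umi = _encode_id(ui, config.umi_length)
            origin = origins[rng.choice(3, p=mix)]
            if origin == "mature":
                gid = cell_mature[rng.integers(len(cell_mature))]
                mol = mature[gid]
                p = int(rng.integers(0, len(mol) - L + 1))
                seq = mol[p : p + L]
                _, junctions = layouts[gid]
                spans = any(p < j < p + L for j in junctions)
                # a junction read whose sequence also occurs in the unspliced
                # molecule (short overhang coinciding with the intron edge)
                # carries no read-level evidence of splicing: ambiguous
                expected = "M" if spans and seq not in nascent[gid] else "A"
            elif origin == "nascent":
                gid = cell_nascent[rng.integers(len(cell_nascent))]
                mol = nascent[gid]
                p = int(rng.integers(0, len(mol) - L + 1))
                seq = mol[p : p + L]
                intronic = bool(intron_masks[gid][p : p + L].any())
                expected = "N" if intronic and seq not in mature[gid] else "A"
            else:
                gid = None
                p = int(intergenic_starts[rng.integers(intergenic_starts.size)])
                seq = genome.seq[p : p + L]
                expected = "filtered"
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SimRead(f"read{ridx}", bc, umi, seq, origin, expected, gid))
            ridx += 1
            if expected != "filtered":
                key = (bc, gid)
                truth_tally[expected][key] = truth_tally[expected].get(key, 0.0) + 1.0

    gene_ids = [g.gene_id for g in genes]
    gidx = {g: j for j, g in enumerate(gene_ids)}
    bidx = {b: i for i, b in enumerate(barcodes)}
    truth: dict[str, CountMatrix] = {}
    for status, tally in truth_tally.items():
        values = np.zeros((len(barcodes), len(gene_ids)))
        for (bc, gid), n in tally.items():
            values[bidx[bc], gidx[gid]] = n
        truth[status] = CountMatrix(values, barcodes, gene_ids)
    for mode in ("cell", "nucleus", "total"):
        truth[mode] = sum_matrices(truth["N"], truth["M"], truth["A"], mode)

    bundle = TruthBundle(genome, list(genes), reads, truth, barcodes, config, seed)
    if config.mismatch_rate or config.del_rate or config.ins_rate:
        noisy = inject_errors(
            [r.seq for r in bundle.reads],
            config.mismatch_rate,
            config.del_rate,
            config.ins_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundle.reads = [
            SimRead(r.name, r.barcode, r.umi, s, r.origin, r.expected_class, r.gene_id)
            for r, s in zip(bundle.reads, noisy)
        ]
    return bundle


def simulate(config: SimConfig, seed: int) -> TruthBundle:
    """Convenience wrapper: reference then reads, both driven by ``seed``."""
    genome, genes = simulate_reference(config, seed)
    return simulate_reads(genome, genes, config, seed + 1)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------


def inject_errors(
    reads: Sequence[str],
    mismatch_rate: float,
    del_rate: float,
    ins_rate: float,
    seed: int,
) -> list[str]:
    """Per-base independent errors in three passes: mismatches, then
    deletions, then insertions.

    A mismatch substitutes uniformly among the three alternative bases; a
    deletion removes the base; an insertion adds a uniform base after the
    position.  Deterministic for a fixed seed; read lengths change under
    indels.
    """
    rng = np.random.default_rng(seed)
    out = []
    for seq in reads:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n = arr.size
        if mismatch_rate > 0 and n:
            hit = rng.random(n) < mismatch_rate
            if hit.any():
                idx = np.nonzero(hit)[0]
                base_idx = np.searchsorted(_BASES, arr[idx])
                shift = rng.integers(1, 4, size=idx.size)
                arr[idx] = _BASES[(base_idx + shift) % 4]
        if del_rate > 0 and arr.size:
            keep = rng.random(arr.size) >= del_rate
            arr = arr[keep]
        if ins_rate > 0 and arr.size:
            ins = rng.random(arr.size) < ins_rate
            if ins.any():
                chunks = []
                for i, b in enumerate(arr):
                    chunks.append(b)
                    if ins[i]:
                        chunks.append(_BASES[rng.integers(0, 4)])
                arr = np.array(chunks, dtype=np.uint8)
        out.append(arr.tobytes().decode("ascii"))
    return out
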