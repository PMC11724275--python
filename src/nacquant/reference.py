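"""Reference parsing and target extraction.

Materializes, from a genome FASTA and a GTF annotation, the two families of
quantification targets:

* **mature** transcripts — exon sequences spliced together (no introns), one
  target per annotated transcript;
* **nascent** transcripts — the contiguous genomic sequence over the full gene
  span (exons *and* introns), one target per gene, named with a configurable
  suffix (default ``-I``).

Minus-strand targets are reverse-complemented so every indexed sequence reads
5'→3' of the mRNA.  GTF coordinates (1-based inclusive on disk) are converted
to 0-based half-open intervals at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cdbg import revcomp
from .errors import ContigNotFoundError, CoordinateError, ValidationError

NASCENT_SUFFIX = "-I"


@dataclass(frozen=True)
class GenomeSequence:
    """A contig: name plus uppercase DNA over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValidationError(f"contig {self.name!r} has empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered, non-overlapping exon intervals (0-based half-open)."""

    transcript_id: str
    gene_id: str
    exons: tuple  # tuple[(start, end), ...] sorted by genomic coordinate

    def __post_init__(self):
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e <= s:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """One gene: strand, member transcripts, genomic span (union of exons)."""

    gene_id: str
    contig: str
    strand: str
    transcripts: tuple

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene without transcripts")

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for t in self.transcripts for s, _ in t.exons]
        ends = [e for t in self.transcripts for _, e in t.exons]
        return min(starts), max(ends)


@dataclass(frozen=True)
class T2GEntry:
    """Row of the target-to-gene table: target, gene, mature|nascent status."""

    target_id: str
    gene_id: str
    status: str

    def __post_init__(self):
        if self.status not in ("mature", "nascent"):
            raise ValidationError(f"bad t2g status {self.status!r}")


@dataclass(frozen=True)
class TranscriptRecord:
    """An extracted target sequence ready for indexing."""

    target_id: str
    gene_id: str
    seq: str
    kind: str  # "mature" | "nascent"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_genome_fasta(path) -> dict[str, GenomeSequence]:
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genome:
        raise ValidationError(f"no sequences in FASTA {path}")
    return genome


def write_fasta(records: Iterable[TranscriptRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.target_id, description=f"gene_id={r.gene_id} kind={r.kind}")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_target_fasta(path, t2g: Iterable[T2GEntry]) -> list[TranscriptRecord]:
    """Read back target sequences, resolving gene and status through a t2g table."""
    by_target = {e.target_id: e for e in t2g}
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entry = by_target.get(rec.id)
        if entry is None:
            raise ValidationError(f"target {rec.id!r} missing from t2g table")
        out.append(TranscriptRecord(rec.id, entry.gene_id, str(rec.seq).upper(), entry.status))
    return out


def read_gtf(path) -> list[GeneModel]:
    """Parse a GTF into gene models.

    Only ``exon`` features are used; ``gene_id`` and ``transcript_id``
    attributes are required.  The annotation is taken as given — no biotype
    filtering is applied.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ValidationError(f"exon without {exc} attribute in {path}") from exc
        rec = transcripts.get(tid)
        if rec is None:
            rec = {"gene_id": gid, "contig": feat.seqid, "strand": feat.strand, "exons": []}
            transcripts[tid] = rec
            order.append(tid)
        elif rec["gene_id"] != gid or rec["contig"] != feat.seqid:
            raise ValidationError(f"transcript {tid!r} spans multiple genes/contigs")
        # GTF is 1-based inclusive; convert to 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))

    genes: dict[str, dict] = {}
    gene_order: list[str] = []
    for tid in order:
        rec = transcripts[tid]
        gid = rec["gene_id"]
        model = TranscriptModel(tid, gid, tuple(rec["exons"]))
        g = genes.get(gid)
        if g is None:
            genes[gid] = {"contig": rec["contig"], "strand": rec["strand"], "transcripts": [model]}
            gene_order.append(gid)
        else:
            if g["strand"] != rec["strand"] or g["contig"] != rec["contig"]:
                raise ValidationError(f"gene {gid!r} has inconsistent strand/contig")
            g["transcripts"].append(model)
    return [
        GeneModel(gid, genes[gid]["contig"], genes[gid]["strand"], tuple(genes[gid]["transcripts"]))
        for gid in gene_order
    ]


def write_gtf(genes: Iterable[GeneModel], path, source: str = "nacquant") -> None:
    """Write gene/transcript/exon features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.contig}\t{source}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                ts = min(x for x, _ in t.exons)
                te = max(x for _, x in t.exons)
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.contig}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for es, ee in t.exons:
                    fh.write(
                        f"{g.contig}\t{source}\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def write_t2g(entries: Iterable[T2GEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.target_id}\t{e.gene_id}\t{e.status}\n")


def read_t2g(path) -> list[T2GEntry]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            target_id, gene_id, status = line.split("\t")
            out.append(T2GEntry(target_id, gene_id, status))
    return out


# ---------------------------------------------------------------------------
# Target extraction
# ---------------------------------------------------------------------------


def _contig_for(genome: Mapping[str, GenomeSequence], gene: GeneModel) -> GenomeSequence:
    try:
        return genome[gene.contig]
    except KeyError:
        raise ContigNotFoundError(
            f"gene {gene.gene_id!r} references contig {gene.contig!r} absent from genome"
        ) from None


def _check_bounds(interval: tuple[int, int], contig: GenomeSequence, what: str) -> None:
    s, e = interval
    if s < 0 or e > len(contig):
        raise CoordinateError(
            f"{what} [{s},{e}) outside contig {contig.name!r} of length {len(contig)}"
        )


def extract_mature_transcripts(
    genome: Mapping[str, GenomeSequence], annotation: Iterable[GeneModel]
) -> list[TranscriptRecord]:
    """Spliced (exon-only) sequence per transcript, strand-adjusted."""
    out = []
    for gene in annotation:
        contig = _contig_for(genome, gene)
        for t in gene.transcripts:
            for exon in t.exons:
                _check_bounds(exon, contig, f"exon of {t.transcript_id!r}")
            seq = "".join(contig.seq[s:e] for s, e in t.exons)
            if gene.strand == "-":
                seq = revcomp(seq)
            out.append(TranscriptRecord(t.transcript_id, gene.gene_id, seq, "mature"))
    return out


def extract_nascent_transcripts(
    genome: Mapping[str, GenomeSequence],
    annotation: Iterable[GeneModel],
    suffix: str = NASCENT_SUFFIX,
) -> list[TranscriptRecord]:
    """Full gene-span sequence (exons + introns) per gene, strand-adjusted."""
    out = []
    for gene in annotation:
        contig = _contig_for(genome, gene)
        span = gene.span
        _check_bounds(span, contig, f"span of {gene.gene_id!r}")
        seq = contig.seq[span[0] : span[1]]
        if gene.strand == "-":
            seq = revcomp(seq)
        out.append(TranscriptRecord(gene.gene_id + suffix, gene.gene_id, seq, "nascent"))
    return out


def build_t2g(
    annotation: Iterable[GeneModel],
    mode: str = "nac",
    nascent_suffix: str = NASCENT_SUFFIX,
) -> list[T2GEntry]:
    """Target-to-gene table: one mature entry per transcript and, in nac mode,
    one nascent entry per gene.  Order is deterministic (annotation order)."""
    entries: list[T2GEntry] = []
    seen: set[str] = set()
    gene_ids: set[str] = set()
    for gene in annotation:
        if gene.gene_id in gene_ids:
            raise ValidationError(f"duplicate gene id {gene.gene_id!r}")
        gene_ids.add(gene.gene_id)
        for t in gene.transcripts:
            if t.transcript_id in seen:
                raise ValidationError(f"duplicate transcript id {t.transcript_id!r}")
            seen.add(t.transcript_id)
            entries.append(T2GEntry(t.transcript_id, gene.gene_id, "mature"))
        if mode == "nac":
            nid = gene.gene_id + nascent_suffix
            if nid in seen:
                raise ValidationError(f"nascent target id {nid!r} collides with a transcript id")
            seen.add(nid)
            entries.append(T2GEntry(nid, gene.gene_id, "nascent"))
    return entries
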