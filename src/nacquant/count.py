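"""UMI collapsing, N/M/A classification and count-matrix emission.

Records sharing a (barcode, UMI) are merged by intersecting their ECs' target
sets (drop on empty intersection).  A single-gene UMI is classified by the
statuses of its compatible targets for that gene:

* only mature targets  → **M** (junction evidence — must come from a spliced
  molecule);
* only the nascent target → **N** (intron evidence — must come from an
  unspliced molecule);
* both                 → **A** (purely exonic — compatible with either).

Multi-gene UMIs are discarded by default; with multimapping enabled, each
gene receives ``1/|genes|`` under the status computed from that gene's own
targets within the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .errors import ValidationError
from .index import Index

SUM_MODES = ("cell", "nucleus", "total")


@dataclass(frozen=True)
class UmiRecord:
    """One (barcode, UMI, EC) observation with its supporting read count."""

    barcode: str
    umi: str
    ec_id: int
    read_count: int = 1

    def __post_init__(self):
        if self.read_count < 1:
            raise ValidationError("read_count must be >= 1")


@dataclass(frozen=True)
class ClassifiedUmi:
    barcode: str
    umi: str
    targets: frozenset  # int target ids, D-list pseudo-target stripped
    genes: frozenset  # gene ids (strings)
    status: Optional[str]  # "N" | "M" | "A" for single-gene UMIs, else None


class CountMatrix:
    """Dense barcode × gene matrix with labels; MatrixMarket round-trip."""

    def __init__(self, values: np.ndarray, barcodes: Sequence[str], genes: Sequence[str]):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(barcodes), len(genes)):
            raise ValidationError(
                f"matrix shape {values.shape} inconsistent with "
                f"{len(barcodes)} barcodes x {len(genes)} genes"
            )
        self.values = values
        self.barcodes = list(barcodes)
        self.genes = list(genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @classmethod
    def zeros(cls, barcodes: Sequence[str], genes: Sequence[str]) -> "CountMatrix":
        return cls(np.zeros((len(barcodes), len(genes))), barcodes, genes)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.barcodes, self.genes)

    def total_per_barcode(self) -> dict[str, float]:
        return dict(zip(self.barcodes, self.values.sum(axis=1)))

    def subset_barcodes(self, keep: Sequence[str]) -> "CountMatrix":
        idx = {b: i for i, b in enumerate(self.barcodes)}
        rows = [idx[b] for b in keep]
        return CountMatrix(self.values[rows, :], list(keep), self.genes)

    def align_to(self, barcodes: Sequence[str], genes: Sequence[str]) -> "CountMatrix":
        """Reindex onto the given labels; missing rows/columns become zeros."""
        out = np.zeros((len(barcodes), len(genes)))
        bidx = {b: i for i, b in enumerate(self.barcodes)}
        gidx = {g: j for j, g in enumerate(self.genes)}
        for i, b in enumerate(barcodes):
            bi = bidx.get(b)
            if bi is None:
                continue
            for j, g in enumerate(genes):
                gj = gidx.get(g)
                if gj is not None:
                    out[i, j] = self.values[bi, gj]
        return CountMatrix(out, barcodes, genes)

    # MatrixMarket layout: <prefix>.mtx + <prefix>.barcodes.txt + <prefix>.genes.txt
    def to_mtx(self, prefix) -> None:
        prefix = str(prefix)
        sparse = scipy.sparse.coo_matrix(self.values)
        scipy.io.mmwrite(prefix + ".mtx", sparse)
        Path(prefix + ".barcodes.txt").write_text("".join(b + "\n" for b in self.barcodes))
        Path(prefix + ".genes.txt").write_text("".join(g + "\n" for g in self.genes))

    @classmethod
    def from_mtx(cls, prefix) -> "CountMatrix":
        prefix = str(prefix)
        values = np.asarray(scipy.io.mmread(prefix + ".mtx").todense())
        barcodes = Path(prefix + ".barcodes.txt").read_text().splitlines()
        genes = Path(prefix + ".genes.txt").read_text().splitlines()
        return cls(values, barcodes, genes)


# ---------------------------------------------------------------------------
# Collapse and classify
# ---------------------------------------------------------------------------


def collapse_umis(records: Iterable[UmiRecord], index: Index) -> list[ClassifiedUmi]:
    """Merge records per (barcode, UMI) and classify the merged target set.

    The D-list pseudo-target is stripped before gene resolution; records left
    with no targets, and UMIs whose ECs have an empty intersection, are
    dropped.
    """
    by_umi: dict[tuple[str, str], Optional[frozenset]] = {}
    order: list[tuple[str, str]] = []
    dlist_id = index.dlist_target_id
    for rec in records:
        targets = index.ec.targets_of(rec.ec_id) - {dlist_id}
        if not targets:
            continue
        key = (rec.barcode, rec.umi)
        if key not in by_umi:
            by_umi[key] = frozenset(targets)
            order.append(key)
        else:
            cur = by_umi[key]
            by_umi[key] = cur & targets if cur is not None else None
    out = []
    for key in order:
        targets = by_umi[key]
        if not targets:
            continue  # conflicting ECs: drop the UMI
        genes, status = classify_targets(targets, index)
        out.append(ClassifiedUmi(key[0], key[1], targets, genes, status))
    return out


def _status_from(statuses: set) -> str:
    if statuses == {"mature"}:
        return "M"
    if statuses == {"nascent"}:
        return "N"
    return "A"


def classify_targets(targets: frozenset, index: Index) -> tuple[frozenset, Optional[str]]:
    """Resolve a target set to its gene set and, if single-gene, its status."""
    if not targets:
        raise ValidationError("cannot classify an empty target set")
    genes = set()
    statuses = set()
    for tid in targets:
        gene = index.gene_of(tid)
        if gene is None:
            raise ValidationError(f"target id {tid} is not a quantifiable target")
        genes.add(gene)
        statuses.add(index.status_of(tid))
    if len(genes) == 1:
        return frozenset(genes), _status_from(statuses)
    return frozenset(genes), None


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def count_matrices(
    classified: Iterable[ClassifiedUmi],
    index: Index,
    *,
    multimapping: bool = False,
    barcodes: Optional[Sequence[str]] = None,
) -> dict[str, CountMatrix]:
    """Tally classified UMIs into N, M and A barcode × gene matrices.

    The gene universe is fixed by the index's t2g table.  With multimapping
    enabled, a multi-gene UMI contributes 1/|genes| to each of its genes, the
    status recomputed per gene from that gene's own targets within the set;
    otherwise multi-gene UMIs are discarded.
    """
    classified = list(classified)
    genes = index.gene_ids
    if barcodes is None:
        barcodes = sorted({c.barcode for c in classified})
    gidx = {g: j for j, g in enumerate(genes)}
    bidx = {b: i for i, b in enumerate(barcodes)}
    mats = {s: np.zeros((len(barcodes), len(genes))) for s in ("N", "M", "A")}
    for c in classified:
        i = bidx.get(c.barcode)
        if i is None:
            continue
        if len(c.genes) == 1:
            (gene,) = c.genes
            mats[c.status][i, gidx[gene]] += 1.0
        elif multimapping:
            w = 1.0 / len(c.genes)
            for gene in c.genes:
                own = frozenset(t for t in c.targets if index.gene_of(t) == gene)
                _, status = classify_targets(own, index)
                mats[status][i, gidx[gene]] += w
    return {s: CountMatrix(v, barcodes, genes) for s, v in mats.items()}


def sum_matrices(
    n: CountMatrix, m: CountMatrix, a: CountMatrix, mode: str
) -> CountMatrix:
    """Combine the N/M/A matrices: cell = M+A, nucleus = N+A, total = N+M+A."""
    if mode not in SUM_MODES:
        raise ValidationError(f"unknown sum mode {mode!r}; expected one of {SUM_MODES}")
    for other in (m, a):
        if other.values.shape != n.values.shape:
            raise ValidationError("matrix shapes differ")
        if other.barcodes != n.barcodes or other.genes != n.genes:
            raise ValidationError("matrix labels differ")
    if mode == "cell":
        v = m.values + a.values
    elif mode == "nucleus":
        v = n.values + a.values
    else:
        v = n.values + m.values + a.values
    return CountMatrix(v, n.barcodes, n.genes)


@dataclass
class TccMatrix:
    """Transcript-compatibility counts: EC (sorted target-name tuple) × barcode."""

    values: np.ndarray
    ec_targets: list  # list[tuple[str, ...]] sorted for reproducibility
    barcodes: list

    def to_mtx(self, prefix) -> None:
        prefix = str(prefix)
        scipy.io.mmwrite(prefix + ".mtx", scipy.sparse.coo_matrix(self.values))
        Path(prefix + ".barcodes.txt").write_text("".join(b + "\n" for b in self.barcodes))
        Path(prefix + ".ec.txt").write_text(
            "".join(f"{i}\t{','.join(ts)}\n" for i, ts in enumerate(self.ec_targets))
        )


def tcc_matrix(classified: Iterable[ClassifiedUmi], index: Index) -> TccMatrix:
    """UMI counts per (EC, barcode); ECs keyed by sorted target-name tuples."""
    classified = list(classified)
    keys = sorted({tuple(sorted(index.name_of(t) for t in c.targets)) for c in classified})
    kidx = {key: i for i, key in enumerate(keys)}
    barcodes = sorted({c.barcode for c in classified})
    bidx = {b: j for j, b in enumerate(barcodes)}
    values = np.zeros((len(keys), len(barcodes)))
    for c in classified:
        key = tuple(sorted(index.name_of(t) for t in c.targets))
        values[kidx[key], bidx[c.barcode]] += 1.0
    return TccMatrix(values, keys, barcodes)
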