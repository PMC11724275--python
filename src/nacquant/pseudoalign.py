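"""Pseudoalignment of reads against the index.

A read is mapped by intersecting the color sets of its canonical k-mers.
K-mers absent from both the color table and the DFK store are skipped (the
classic pseudoalignment contract — absence is not evidence against any
target).  A single DFK hit anywhere in the read is fatal: the read is masked
out as likely external.  Under ``dfk_onlist`` the read is instead kept and a
reserved D-list pseudo-target is added to its equivalence class, so that
discarded-by-DFK reads can be distinguished from genuinely unmappable ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import zip_longest
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .cdbg import iter_canonical_kmers
from .count import UmiRecord
from .errors import ValidationError
from .index import Index


@dataclass(frozen=True)
class MappingResult:
    status: str  # "mapped" | "unmapped" | "dfk_filtered"
    ec_targets: frozenset  # target ids; empty unless mapped
    dfk_hit: bool


@dataclass(frozen=True)
class BarcodeLayout:
    """10x-style technical read layout: R1 = barcode + UMI, R2 = cDNA."""

    barcode_length: int = 16
    umi_length: int = 12


def pseudoalign_read(index: Index, read: str, dfk_onlist: bool = False) -> MappingResult:
    """Map one read to an equivalence-class target set.

    Reads shorter than k are unmapped (not an error).  The DFK check precedes
    color intersection and, unless ``dfk_onlist`` is set, short-circuits.
    """
    read = read.upper()
    kmers = [km for _, km in iter_canonical_kmers(read, index.k)]
    dfk_hit = any(km in index.dfks for km in kmers)
    if dfk_hit and not dfk_onlist:
        return MappingResult("dfk_filtered", frozenset(), True)
    inter: Optional[frozenset] = None
    for km in kmers:
        colors = index.colors.get(km)
        if colors is None:
            continue  # absent from colors (and not fatal): skip
        inter = colors if inter is None else inter & colors
        if not inter:
            return MappingResult("unmapped", frozenset(), dfk_hit)
    if inter is None:
        # no colored k-mer at all
        if dfk_hit and dfk_onlist:
            return MappingResult("mapped", frozenset({index.dlist_target_id}), True)
        return MappingResult("unmapped", frozenset(), dfk_hit)
    if dfk_hit and dfk_onlist:
        inter = inter | {index.dlist_target_id}
    return MappingResult("mapped", inter, dfk_hit)


def map_reads(
    index: Index,
    reads: Iterable[tuple[str, str, str]],
    *,
    dfk_onlist: bool = False,
    on_list: Optional[set] = None,
) -> tuple[list[UmiRecord], dict]:
    """Map ``(barcode, umi, sequence)`` triples to UMI records.

    Returns one record per distinct ``(barcode, umi, ec)`` with its read
    count, sorted by (barcode, umi, ec), plus mapping statistics.  Barcodes
    outside ``on_list`` (if given) are dropped before mapping.
    """
    stats = {
        "n_reads": 0,
        "mapped": 0,
        "unmapped": 0,
        "dfk_filtered": 0,
        "dfk_onlist_only": 0,
        "barcode_filtered": 0,
    }
    counts: dict[tuple[str, str, int], int] = {}
    for barcode, umi, seq in reads:
        stats["n_reads"] += 1
        if on_list is not None and barcode not in on_list:
            stats["barcode_filtered"] += 1
            continue
        res = pseudoalign_read(index, seq, dfk_onlist=dfk_onlist)
        if res.status == "mapped":
            stats["mapped"] += 1
            if res.ec_targets == {index.dlist_target_id}:
                stats["dfk_onlist_only"] += 1
            ec = index.get_ec(res.ec_targets)
            counts[(barcode, umi, ec)] = counts.get((barcode, umi, ec), 0) + 1
        elif res.status == "dfk_filtered":
            stats["dfk_filtered"] += 1
        else:
            stats["unmapped"] += 1
    records = [
        UmiRecord(bc, umi, ec, n) for (bc, umi, ec), n in sorted(counts.items())
    ]
    return records, stats


def iter_fastq_pairs(
    r1_path, r2_path, layout: BarcodeLayout
) -> Iterator[tuple[str, str, str]]:
    """Yield (barcode, umi, cdna) from paired FASTQ files."""
    r1 = SeqIO.parse(str(r1_path), "fastq")
    r2 = SeqIO.parse(str(r2_path), "fastq")
    need = layout.barcode_length + layout.umi_length
    for i, (a, b) in enumerate(zip_longest(r1, r2), start=1):
        if a is None or b is None:
            raise ValidationError(f"FASTQ files differ in length (record {i})")
        tech = str(a.seq).upper()
        if len(tech) < need:
            raise ValidationError(
                f"record {i}: technical read of length {len(tech)} < "
                f"barcode+UMI length {need}"
            )
        yield tech[: layout.barcode_length], tech[layout.barcode_length : need], str(b.seq)


def map_fastq(
    index: Index,
    r1_path,
    r2_path,
    layout: BarcodeLayout = BarcodeLayout(),
    *,
    dfk_onlist: bool = False,
    on_list: Optional[set] = None,
) -> tuple[list[UmiRecord], dict]:
    """Map paired FASTQ files (R1 technical, R2 cDNA) to UMI records."""
    return map_reads(
        index, iter_fastq_pairs(r1_path, r2_path, layout), dfk_onlist=dfk_onlist, on_list=on_list
    )


def write_records_tsv(records: Iterable[UmiRecord], path) -> None:
    """Plain-text analog of a BUS file: barcode, UMI, EC id, read count."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.barcode}\t{r.umi}\t{r.ec_id}\t{r.read_count}\n")


def read_records_tsv(path) -> list[UmiRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            bc, umi, ec, n = line.rstrip("\n").split("\t")
            out.append(UmiRecord(bc, umi, int(ec), int(n)))
    return out


def write_stats_json(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
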