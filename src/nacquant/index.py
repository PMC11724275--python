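"""The quantification index.

Bundles the target cdBG, the per-k-mer color table (canonical k-mer → set of
target ids containing it in either orientation), the DFK store (kept apart
from the colors and uncolored), the target-to-gene table, and a dynamically
allocated equivalence-class table: an EC id is only created the first time a
read is found to use that target set.

Two index modes exist:

* ``standard`` — mature transcripts only (the classic transcriptome index);
* ``nac``      — mature plus nascent (full gene span) targets, enabling
  nascent/mature/ambiguous classification of UMIs.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterable, Mapping, Optional, Sequence

from .cdbg import CdBG, iter_canonical_kmers
from .dlist import DfkExtractionReport, DfkSet, extract_dfks
from .errors import ValidationError
from .reference import (
    GeneModel,
    GenomeSequence,
    T2GEntry,
    TranscriptRecord,
    build_t2g,
    extract_mature_transcripts,
    extract_nascent_transcripts,
)

INDEX_FORMAT = "nacquant-index"
INDEX_VERSION = 1
DLIST_TARGET_NAME = "__dlist__"


class EcTable:
    """Bidirectional EC id ↔ target-set table with on-demand allocation."""

    def __init__(self):
        self._by_set: dict[frozenset, int] = {}
        self._by_id: list[frozenset] = []

    def get(self, target_set: Iterable[int]) -> int:
        ts = frozenset(target_set)
        if not ts:
            raise ValueError("cannot allocate an EC for an empty target set")
        ec = self._by_set.get(ts)
        if ec is None:
            ec = len(self._by_id)
            self._by_set[ts] = ec
            self._by_id.append(ts)
        return ec

    def targets_of(self, ec_id: int) -> frozenset:
        return self._by_id[ec_id]

    def __len__(self) -> int:
        return len(self._by_id)

    def items(self):
        return enumerate(self._by_id)


class Index:
    """Target sequences + colors + DFKs + t2g + dynamic EC table."""

    def __init__(
        self,
        k: int,
        mode: str,
        targets: Sequence[TranscriptRecord],
        dfks: Optional[DfkSet] = None,
        t2g: Optional[Sequence[T2GEntry]] = None,
        overhang: int = 1,
        dfk_report: Optional[DfkExtractionReport] = None,
    ):
        if mode not in ("standard", "nac"):
            raise ValidationError(f"unknown index mode {mode!r}")
        names = [t.target_id for t in targets]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate target ids")
        self.k = k
        self.mode = mode
        self.targets = list(targets)
        self.overhang = overhang
        self.dfks = dfks if dfks is not None else DfkSet()
        self.dfk_report = dfk_report
        self.t2g = list(t2g) if t2g is not None else self._default_t2g()
        self._gene_of = {e.target_id: e.gene_id for e in self.t2g}
        self._status_of = {e.target_id: e.status for e in self.t2g}
        for t in self.targets:
            if t.target_id not in self._gene_of:
                raise ValidationError(f"target {t.target_id!r} missing from t2g")
        self.cdbg = CdBG.build((t.seq for t in self.targets), k)
        self.colors: dict[str, frozenset[int]] = self._build_colors()
        self.ec = EcTable()

    def _default_t2g(self) -> list[T2GEntry]:
        return [T2GEntry(t.target_id, t.gene_id, t.kind) for t in self.targets]

    def _build_colors(self) -> dict[str, frozenset[int]]:
        acc: dict[str, set[int]] = {}
        for tid, rec in enumerate(self.targets):
            for _, km in iter_canonical_kmers(rec.seq, self.k):
                acc.setdefault(km, set()).add(tid)
        return {km: frozenset(s) for km, s in acc.items()}

    # -- identity ----------------------------------------------------------

    @property
    def target_names(self) -> list[str]:
        return [t.target_id for t in self.targets]

    @property
    def dlist_target_id(self) -> int:
        """Reserved pseudo-target id used under --dfk-onlist; never in t2g."""
        return len(self.targets)

    def name_of(self, target_id: int) -> str:
        if target_id == self.dlist_target_id:
            return DLIST_TARGET_NAME
        return self.targets[target_id].target_id

    def gene_of(self, target_id: int) -> Optional[str]:
        if target_id == self.dlist_target_id:
            return None
        return self._gene_of[self.targets[target_id].target_id]

    def status_of(self, target_id: int) -> Optional[str]:
        if target_id == self.dlist_target_id:
            return None
        return self._status_of[self.targets[target_id].target_id]

    @property
    def gene_ids(self) -> list[str]:
        seen, out = set(), []
        for e in self.t2g:
            if e.gene_id not in seen:
                seen.add(e.gene_id)
                out.append(e.gene_id)
        return out

    # -- queries -----------------------------------------------------------

    def color_of(self, kmer: str) -> Optional[frozenset[int]]:
        from .cdbg import canonical, is_acgt

        if len(kmer) != self.k or not is_acgt(kmer):
            return None
        return self.colors.get(canonical(kmer))

    def get_ec(self, target_set: Iterable[int]) -> int:
        return self.ec.get(target_set)

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": INDEX_FORMAT,
            "version": INDEX_VERSION,
            "k": self.k,
            "mode": self.mode,
            "overhang": self.overhang,
            "targets": [
                {"id": t.target_id, "gene": t.gene_id, "kind": t.kind, "seq": t.seq}
                for t in self.targets
            ],
            "t2g": [[e.target_id, e.gene_id, e.status] for e in self.t2g],
            "dfks": self.dfks.to_dict(),
            "dfk_report": self.dfk_report.to_dict() if self.dfk_report else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "Index":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != INDEX_FORMAT:
            raise ValidationError(f"{path} is not a {INDEX_FORMAT} file")
        if payload.get("version") != INDEX_VERSION:
            raise ValidationError(f"unsupported index version {payload.get('version')}")
        targets = [
            TranscriptRecord(t["id"], t["gene"], t["seq"], t["kind"]) for t in payload["targets"]
        ]
        t2g = [T2GEntry(*row) for row in payload["t2g"]]
        dfks = DfkSet.from_dict(payload["dfks"])
        report = (
            DfkExtractionReport(**payload["dfk_report"]) if payload.get("dfk_report") else None
        )
        return cls(
            payload["k"],
            payload["mode"],
            targets,
            dfks=dfks,
            t2g=t2g,
            overhang=payload["overhang"],
            dfk_report=report,
        )


def build_index(
    targets: Sequence[TranscriptRecord],
    k: int,
    *,
    mode: str = "standard",
    dlist: Optional[Iterable] = None,
    overhang: int = 1,
    t2g: Optional[Sequence[T2GEntry]] = None,
) -> Index:
    """Assemble an :class:`Index` from target records.

    Targets shorter than ``k`` are skipped with a warning.  If ``dlist``
    sequences are given, DFKs are extracted against the target cdBG with the
    requested overhang and stored (uncolored) in the index.
    """
    if not targets:
        raise ValidationError("no targets")
    usable = []
    for t in targets:
        if len(t.seq) < k:
            warnings.warn(f"target {t.target_id!r} shorter than k={k}; skipped", stacklevel=2)
        else:
            usable.append(t)
    index = Index(k, mode, usable, t2g=t2g, overhang=overhang)
    if dlist is not None:
        dfks, report = extract_dfks(dlist, index.cdbg, overhang=overhang)
        index.dfks = dfks
        index.dfk_report = report
    return index


def build_reference_index(
    genome: Mapping[str, GenomeSequence],
    annotation: Sequence[GeneModel],
    k: int,
    *,
    mode: str = "nac",
    dlist: str | Iterable | None = "genome",
    overhang: int = 1,
    nascent_suffix: str = "-I",
) -> Index:
    """Extract targets from genome+annotation and build the index.

    ``dlist="genome"`` (the default) uses the genome FASTA itself as the
    D-list; pass ``None`` to disable DFK extraction or any sequence collection
    to use a custom D-list.
    """
    records = extract_mature_transcripts(genome, annotation)
    if mode == "nac":
        records = records + extract_nascent_transcripts(genome, annotation, suffix=nascent_suffix)
    t2g = build_t2g(annotation, mode=mode, nascent_suffix=nascent_suffix)
    if isinstance(dlist, str) and dlist == "genome":
        dlist = list(genome.values())
    return build_index(records, k, mode=mode, dlist=dlist, overhang=overhang, t2g=t2g)
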