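"""Distinguishing flanking k-mer (DFK) extraction from a D-list.

A D-list is a set of sequences (by default the genome the targets were derived
from) that is scanned against the target cdBG.  Every maximal run of
consecutive D-list k-mers present in the graph — a stretch of sequence at
least k bases long shared with the targets — is flanked, on each side, by
k-mers present in the D-list but absent from the graph.  The first ``h`` such
k-mers on each side (``h`` = overhang, default 1) are collected as DFKs.

DFKs are by construction disjoint from the graph's k-mer set.  They are kept
uncolored and outside the color table: during pseudoalignment a read touching
any DFK is masked out as likely external to the indexed targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .cdbg import CdBG, canonical, valid_kmer_starts


@dataclass(frozen=True)
class CommonRun:
    """Maximal run of consecutive k-mer start positions shared with the cdBG.

    ``start``/``end`` are 0-based half-open k-mer *start* positions in the
    D-list sequence; the run spans ``end - start + k - 1`` bases.
    """

    seq_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty common run")


@dataclass(frozen=True)
class DfkProvenance:
    """Where a DFK was found in the D-list.

    ``anchor_pos`` is the position (in the same D-list sequence) of the
    run-boundary graph k-mer the flank chain is attached to; it allows
    attributing the DFK to a unitig of the cdBG.
    """

    seq_id: str
    pos: int
    side: str  # "upstream" | "downstream"
    rank: int  # 1..h, distance from the run boundary
    anchor_pos: int


class DfkSet:
    """Set of canonical DFKs with per-k-mer provenance."""

    def __init__(self):
        self._kmers: dict[str, list[DfkProvenance]] = {}

    def add(self, kmer: str, prov: DfkProvenance) -> None:
        self._kmers.setdefault(kmer, []).append(prov)

    @property
    def kmers(self) -> set[str]:
        return set(self._kmers)

    def provenance(self, kmer: str) -> list[DfkProvenance]:
        return list(self._kmers[kmer])

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self._kmers if kmer else False

    def __len__(self) -> int:
        return len(self._kmers)

    def __iter__(self):
        return iter(self._kmers)

    def __eq__(self, other) -> bool:
        return isinstance(other, DfkSet) and self._kmers.keys() == other._kmers.keys()

    def to_dict(self) -> dict:
        return {
            km: [[p.seq_id, p.pos, p.side, p.rank, p.anchor_pos] for p in provs]
            for km, provs in sorted(self._kmers.items())
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DfkSet":
        out = cls()
        for km, provs in d.items():
            for sid, pos, side, rank, anchor in provs:
                out.add(km, DfkProvenance(sid, pos, side, rank, anchor))
        return out

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for km in sorted(self._kmers):
                p = self._kmers[km][0]
                fh.write(f">dfk|{p.seq_id}|{p.pos}|{p.side}|rank={p.rank}\n{km}\n")


@dataclass
class DfkExtractionReport:
    """Summary statistics of one DFK extraction."""

    n_k: int  # unique k-mers in the cdBG
    m_k: int  # unique k-mers in the D-list
    dfk_count: int
    run_count: int
    overhang: int

    def to_dict(self) -> dict:
        return {
            "n_k": self.n_k,
            "m_k": self.m_k,
            "dfk_count": self.dfk_count,
            "run_count": self.run_count,
            "overhang": self.overhang,
        }


def find_common_runs(dlist_seq: str, cdbg: CdBG, seq_id: str = "dlist") -> list[CommonRun]:
    """Maximal runs of consecutive D-list k-mers present in the cdBG.

    Windows containing non-ACGT characters are never part of a run and break
    runs just like absent k-mers do.  Sequences shorter than k yield no runs.
    """
    k = cdbg.k
    seq = dlist_seq.upper()
    runs: list[CommonRun] = []
    run_start = None
    prev = None
    for i in valid_kmer_starts(seq, k):
        i = int(i)
        present = canonical(seq[i : i + k]) in cdbg
        if present:
            if run_start is not None and prev == i - 1:
                prev = i
            else:
                if run_start is not None:
                    runs.append(CommonRun(seq_id, run_start, prev + 1))
                run_start, prev = i, i
        else:
            if run_start is not None:
                runs.append(CommonRun(seq_id, run_start, prev + 1))
                run_start = None
    if run_start is not None:
        runs.append(CommonRun(seq_id, run_start, prev + 1))
    return runs


def _as_named_seqs(dlist) -> list[tuple[str, str]]:
    """Accept GenomeSequence-likes, (name, seq) pairs, or a name->seq mapping."""
    if isinstance(dlist, Mapping):
        return [(str(n), s.upper()) for n, s in dlist.items()]
    out = []
    for i, item in enumerate(dlist):
        if isinstance(item, tuple):
            name, seq = item
        elif hasattr(item, "name") and hasattr(item, "seq"):
            name, seq = item.name, item.seq
        else:
            name, seq = f"dlist{i}", item
        out.append((str(name), str(seq).upper()))
    return out


def extract_dfks(
    dlist: Iterable, cdbg: CdBG, overhang: int = 1
) -> tuple[DfkSet, DfkExtractionReport]:
    """Extract DFKs from D-list sequences against a target cdBG.

    For each common run, the up-to-``overhang`` consecutive k-mers immediately
    upstream and downstream in the D-list are canonicalized and added to the
    DFK set.  Flank extension on a side stops at the sequence boundary, at a
    window containing a non-ACGT character, or at a k-mer that is itself in
    the cdBG (such a k-mer cannot be a DFK; by run maximality this only occurs
    through canonicalization coincidences or at a neighbouring run).
    """
    if overhang < 1:
        raise ValueError(f"overhang must be >= 1, got {overhang}")
    k = cdbg.k
    seqs = _as_named_seqs(dlist)
    dfks = DfkSet()
    m_kmers: set[str] = set()
    run_count = 0
    for seq_id, seq in seqs:
        valid = set(int(i) for i in valid_kmer_starts(seq, k))
        for i in valid:
            m_kmers.add(canonical(seq[i : i + k]))
        for run in find_common_runs(seq, cdbg, seq_id=seq_id):
            run_count += 1
            for side, anchor, step in (
                ("upstream", run.start, -1),
                ("downstream", run.end - 1, +1),
            ):
                for rank in range(1, overhang + 1):
                    pos = anchor + step * rank
                    if pos not in valid:
                        break  # sequence boundary or non-ACGT window
                    km = canonical(seq[pos : pos + k])
                    if km in cdbg:
                        break  # in-graph k-mer terminates flank extension
                    dfks.add(km, DfkProvenance(seq_id, pos, side, rank, anchor))
    report = DfkExtractionReport(
        n_k=cdbg.n_kmers,
        m_k=len(m_kmers),
        dfk_count=len(dfks),
        run_count=run_count,
        overhang=overhang,
    )
    return dfks, report


def attribute_dfks_to_unitigs(dfks: DfkSet, cdbg: CdBG, dlist) -> dict[int, set[str]]:
    """Map each unitig id to the set of DFKs flanking it.

    A DFK is attributed to the unitig containing the run-boundary graph k-mer
    recorded in its provenance (the k-mer it is chained to in the D-list).
    Used for verifying the per-unitig worst-case flank capacity.
    """
    seqs = dict(_as_named_seqs(dlist))
    k = cdbg.k
    out: dict[int, set[str]] = {}
    for km in dfks:
        for p in dfks.provenance(km):
            anchor_kmer = seqs[p.seq_id][p.anchor_pos : p.anchor_pos + k]
            uid = cdbg.unitig_of(anchor_kmer)
            if uid is not None:
                out.setdefault(uid, set()).add(km)
    return out


def attribute_dfks_to_anchors(dfks: DfkSet, cdbg: CdBG, dlist) -> dict[str, set[str]]:
    """Map each anchor *vertex* (canonical run-boundary k-mer) to its DFKs.

    The flank-capacity bound is a per-vertex statement: a D-list run can
    diverge from the graph at any k-mer of a unitig, so a long unitig can
    anchor flanks at many of its vertices while each single vertex is limited
    by its |alphabet| extensions per side.
    """
    seqs = dict(_as_named_seqs(dlist))
    k = cdbg.k
    out: dict[str, set[str]] = {}
    for km in dfks:
        for p in dfks.provenance(km):
            anchor = canonical(seqs[p.seq_id][p.anchor_pos : p.anchor_pos + k])
            out.setdefault(anchor, set()).add(km)
    return out


def per_side_flank_capacity(require_graph_continuation: bool, alphabet: str = "ACGT") -> int:
    """Maximum DFKs on one side of a unitig, by exhaustive configuration scan.

    On one side of a unitig-terminal k-mer there are ``|alphabet|`` candidate
    flanking k-mers (one per character).  Each candidate is either present in
    the de Bruijn graph or available to the D-list as a DFK.  The function
    enumerates every subset of candidates as the "in-graph" set and returns
    the largest number of remaining candidates, i.e. the per-side DFK
    capacity.  With ``require_graph_continuation=True`` only configurations
    where the side retains at least one in-graph continuation are considered
    (the generic case for a unitig embedded in a larger graph); without it,
    free ends (tips) are allowed and every candidate may be a DFK.
    """
    from itertools import chain, combinations

    candidates = tuple(alphabet)
    best = 0
    subsets = chain.from_iterable(
        combinations(candidates, r) for r in range(len(candidates) + 1)
    )
    for in_graph in subsets:
        if require_graph_continuation and len(in_graph) == 0:
            continue
        best = max(best, len(candidates) - len(in_graph))
    return best
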