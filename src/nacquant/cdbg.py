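"""Compact de Bruijn graph over canonical k-mers.

The graph is bidirected: a k-mer and its reverse complement are represented by
a single *canonical* k-mer, the lexicographic minimum of the two.  Maximal
non-branching paths are compacted into unitigs; a k-mer lookup table maps every
canonical k-mer to its (unitig, offset, orientation) location.

This is a plain-hash-table reference implementation: it favours clarity and
determinism (unitig ids are assigned by lexicographic order of the
canonically-oriented unitig sequence) over the minimizer/MPHF machinery used
by production indexers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .errors import EmptyGraphError

ALPHABET = "ACGT"
_ACGT = frozenset(ALPHABET)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form of a k-mer: min(kmer, revcomp(kmer)) lexicographically.

    Idempotent, and ``canonical(x) == canonical(revcomp(x))``.  The caller is
    responsible for only passing ACGT strings; windows containing other
    characters should be dropped (see :func:`iter_canonical_kmers`).
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_acgt(seq: str) -> bool:
    return all(c in _ACGT for c in seq)


def valid_kmer_starts(seq: str, k: int) -> np.ndarray:
    """0-based start positions of length-k windows made only of A/C/G/T."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    bad = ~((arr == 65) | (arr == 67) | (arr == 71) | (arr == 84))
    prefix = np.concatenate([[0], np.cumsum(bad)])
    return np.nonzero(prefix[k:] - prefix[:-k] == 0)[0].astype(np.int64)


def iter_canonical_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield ``(start, canonical_kmer)`` for every valid window of ``seq``."""
    for i in valid_kmer_starts(seq, k):
        i = int(i)
        yield i, canonical(seq[i : i + k])


@dataclass(frozen=True)
class Unitig:
    """A maximal non-branching path, stored canonically oriented."""

    id: int
    seq: str

    def kmer_count(self, k: int) -> int:
        return len(self.seq) - k + 1


class KmerHit(NamedTuple):
    unitig_id: int
    offset: int
    orientation: str  # "forward" if the queried k-mer matches the unitig as stored


class CdBG:
    """Compact de Bruijn graph with canonical k-mer lookup (``Map``)."""

    def __init__(self, k: int, unitigs: Sequence[Unitig], kmer_table: dict):
        self.k = k
        self.unitigs = list(unitigs)
        # canonical k-mer -> (unitig id, offset)
        self._table = kmer_table

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, sequences: Iterable[str], k: int) -> "CdBG":
        """Build the cdBG over ``sequences``.

        ``k`` must be odd (so no k-mer equals its own reverse complement) and
        greater than 1.  Raises :class:`EmptyGraphError` if no sequence
        contributes a single valid k-mer.
        """
        if k <= 1 or k % 2 == 0:
            raise ValueError(f"k must be an odd integer > 1, got {k}")
        kmers: set[str] = set()
        for seq in sequences:
            seq = seq.upper()
            for _, km in iter_canonical_kmers(seq, k):
                kmers.add(km)
        if not kmers:
            raise EmptyGraphError(f"no sequence contains a valid k-mer of length {k}")

        def succs(x: str) -> list[str]:
            suf = x[1:]
            return [suf + c for c in ALPHABET if canonical(suf + c) in kmers]

        def preds(x: str) -> list[str]:
            pre = x[:-1]
            return [c + pre for c in ALPHABET if canonical(c + pre) in kmers]

        visited: set[str] = set()
        unitig_seqs: list[str] = []
        for start in sorted(kmers):
            if start in visited:
                continue
            in_path = {start}
            right: list[str] = []
            cur = start
            while True:
                nxt_l = succs(cur)
                if len(nxt_l) != 1:
                    break
                nxt = nxt_l[0]
                if len(preds(nxt)) != 1:
                    break
                cn = canonical(nxt)
                if cn in in_path or cn in visited:
                    break
                right.append(nxt)
                in_path.add(cn)
                cur = nxt
            left: list[str] = []
            cur = start
            while True:
                prv_l = preds(cur)
                if len(prv_l) != 1:
                    break
                prv = prv_l[0]
                if len(succs(prv)) != 1:
                    break
                cp = canonical(prv)
                if cp in in_path or cp in visited:
                    break
                left.append(prv)
                in_path.add(cp)
                cur = prv
            seq = "".join(p[0] for p in reversed(left)) + start + "".join(s[-1] for s in right)
            seq = min(seq, revcomp(seq))
            unitig_seqs.append(seq)
            visited |= in_path

        unitig_seqs.sort()
        unitigs = [Unitig(i, s) for i, s in enumerate(unitig_seqs)]
        table: dict[str, tuple[int, int]] = {}
        for u in unitigs:
            for off in range(len(u.seq) - k + 1):
                cm = canonical(u.seq[off : off + k])
                assert cm not in table, "k-mer shared between unitigs"
                table[cm] = (u.id, off)
        assert len(table) == len(kmers)
        return cls(k, unitigs, table)

    # -- queries -----------------------------------------------------------

    @property
    def n_kmers(self) -> int:
        """Number of unique canonical k-mers in the graph (N_k)."""
        return len(self._table)

    def __contains__(self, kmer: str) -> bool:
        """Membership by canonical form; accepts either orientation."""
        if len(kmer) != self.k or not is_acgt(kmer):
            return False
        return canonical(kmer) in self._table

    def kmers(self) -> Iterator[str]:
        return iter(self._table)

    def lookup(self, kmer: str) -> Optional[KmerHit]:
        """``Map(s, U)``: locate ``kmer`` (either orientation) in the graph."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        if not is_acgt(kmer):
            return None
        hit = self._table.get(canonical(kmer))
        if hit is None:
            return None
        uid, off = hit
        stored = self.unitigs[uid].seq[off : off + self.k]
        orientation = "forward" if kmer == stored else "reverse"
        return KmerHit(uid, off, orientation)

    def unitig_of(self, kmer: str) -> Optional[int]:
        hit = self._table.get(canonical(kmer)) if (len(kmer) == self.k and is_acgt(kmer)) else None
        return hit[0] if hit is not None else None
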