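"""Independent brute-force oracles and random-instance generators.

Everything here deliberately avoids the library's graph/run machinery:
membership is computed from raw substrings, compaction validity is checked
against the structural definition, and metrics are computed with naive
double loops.
"""

from __future__ import annotations

import numpy as np

ACGT = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def is_acgt(s: str) -> bool:
    return all(c in ACGT for c in s)


def brute_kmer_set(seqs, k) -> set:
    """Canonical k-mers of a sequence collection, by raw substring scan."""
    out = set()
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if is_acgt(w):
                out.add(canon(w))
    return out


def brute_colors(target_seqs, kmer, k) -> set:
    """Targets containing the k-mer in either orientation, by substring test."""
    return {
        t
        for t, seq in enumerate(target_seqs)
        if kmer in seq or rc(kmer) in seq
    }


def brute_ec(target_seqs, read, k) -> set | None:
    """Brute-force pseudoalignment: intersect per-k-mer substring colors.

    Returns None when the read has no k-mer present in any target.
    """
    inter = None
    for i in range(len(read) - k + 1):
        w = read[i : i + k]
        if not is_acgt(w):
            continue
        colors = brute_colors(target_seqs, w, k)
        if not colors:
            continue
        inter = colors if inter is None else inter & colors
    return inter


def oracle_dfks(dlist_named, target_seqs, k, h) -> set:
    """DFKs by definition: scan every D-list k-mer, mark membership against
    the raw target k-mer set, take up to h flanks around each shared run."""
    members = brute_kmer_set(target_seqs, k)
    dfks = set()
    for _, seq in dlist_named:
        seq = seq.upper()
        n = len(seq)

        def present(i):
            w = seq[i : i + k]
            return len(w) == k and is_acgt(w) and canon(w) in members

        i = 0
        while i <= n - k:
            if not present(i):
                i += 1
                continue
            j = i
            while j + 1 <= n - k and present(j + 1):
                j += 1
            for anchor, step in ((i, -1), (j, +1)):
                for r in range(1, h + 1):
                    p = anchor + step * r
                    w = seq[p : p + k]
                    if p < 0 or p > n - k or not is_acgt(w):
                        break
                    if canon(w) in members:
                        break
                    dfks.add(canon(w))
            i = j + 1
    return dfks


def assert_valid_compaction(cdbg, input_seqs):
    """Structural check that a cdBG is a correct maximal compaction.

    Verifies (i) k-mer conservation against a raw substring scan, (ii) each
    unitig is a walk whose internal junctions are unique in both directions,
    and (iii) maximality: no unitig end admits a unique bidirectional
    extension to an unvisited vertex.
    """
    k = cdbg.k
    kmers = brute_kmer_set(input_seqs, k)
    table_kmers = set(cdbg.kmers())
    assert table_kmers == kmers, "k-mer conservation violated"

    def succs(x):
        return [x[1:] + c for c in ACGT if canon(x[1:] + c) in kmers]

    def preds(x):
        return [c + x[:-1] for c in ACGT if canon(c + x[:-1]) in kmers]

    seen = set()
    for u in cdbg.unitigs:
        path = [u.seq[i : i + k] for i in range(len(u.seq) - k + 1)]
        canon_path = [canon(p) for p in path]
        assert len(set(canon_path)) == len(canon_path), "repeated vertex in unitig"
        for a, b in zip(path, path[1:]):
            assert succs(a) == [b], f"branch inside unitig {u.seq}"
            assert preds(b) == [a], f"non-unique junction in {u.seq}"
        # maximality at both ends
        first, last = path[0], path[-1]
        nxt = succs(last)
        if len(nxt) == 1 and len(preds(nxt[0])) == 1:
            assert canon(nxt[0]) in canon_path, f"unitig {u.seq} extendable right"
        prv = preds(first)
        if len(prv) == 1 and len(succs(prv[0])) == 1:
            assert canon(prv[0]) in canon_path, f"unitig {u.seq} extendable left"
        seen.update(canon_path)
    assert seen == kmers


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(ACGT[i] for i in rng.integers(0, 4, size=length))


def random_instance(rng: np.random.Generator, k=5, with_n=False):
    """A random (targets, D-list) pair with genuine shared runs.

    Targets are short random sequences; D-list sequences are random
    backgrounds with target fragments embedded, so common runs with real
    flanks occur frequently.  Occasionally an 'N' is planted to exercise
    non-ACGT breaks.
    """
    n_targets = int(rng.integers(1, 4))
    targets = [random_dna(rng, int(rng.integers(6 * k, 16 * k))) for _ in range(n_targets)]
    dlist = []
    for d in range(int(rng.integers(1, 4))):
        bg = list(random_dna(rng, int(rng.integers(8 * k, 20 * k))))
        for _ in range(int(rng.integers(1, 4))):
            t = targets[rng.integers(n_targets)]
            frag_len = int(rng.integers(k - 2, min(len(t), 6 * k)))
            fs = int(rng.integers(0, len(t) - frag_len + 1))
            frag = t[fs : fs + frag_len]
            pos = int(rng.integers(0, len(bg) - frag_len + 1))
            bg[pos : pos + frag_len] = list(frag)
        if with_n and rng.random() < 0.3:
            bg[int(rng.integers(len(bg)))] = "N"
        dlist.append((f"d{d}", "".join(bg)))
    return targets, dlist


# ---------------------------------------------------------------------------
# Naive metric implementations
# ---------------------------------------------------------------------------


def naive_rmse_fpr_fnr(y, yhat):
    n, m = y.shape
    se = 0.0
    fp = 0
    fn = 0
    for i in range(n):
        for j in range(m):
            se += (y[i, j] - yhat[i, j]) ** 2
            if y[i, j] == 0 and yhat[i, j] > 0:
                fp += 1
            if y[i, j] > 0 and yhat[i, j] == 0:
                fn += 1
    return (se / (n * m)) ** 0.5, fp / (n * m), fn / (n * m)


def average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def naive_pearson(x, y):
    n = len(x)
    if n < 2:
        return float("nan")
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / (sxx * syy) ** 0.5


def naive_spearman_filtered(y_row, yhat_row, strict=False):
    """Rank-then-Pearson on pairs excluding (0,0) (or zero-in-either)."""
    if strict:
        pairs = [(a, b) for a, b in zip(y_row, yhat_row) if a != 0 and b != 0]
    else:
        pairs = [(a, b) for a, b in zip(y_row, yhat_row) if (a, b) != (0, 0)]
    if len(pairs) < 2:
        return float("nan")
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    return naive_pearson(average_ranks(xs), average_ranks(ys))
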