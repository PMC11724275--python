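import numpy as np
import pytest

import oracles
from nacquant import CdBG, canonical, extract_dfks, find_common_runs
from nacquant.dlist import (
    attribute_dfks_to_anchors,
    attribute_dfks_to_unitigs,
    per_side_flank_capacity,
)


@pytest.fixture(scope="module")
def toy_cdbg():
    return CdBG.build(["AAAAACCCCC"], 5)


class TestCommonRuns:
    def test_single_run_with_flanks(self, toy_cdbg):
        runs = find_common_runs("GGAAAAACCCCCTT", toy_cdbg)
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end) == (2, 8)
        # maximality: neighbours of the run are absent from the graph
        seq = "GGAAAAACCCCCTT"
        assert seq[1:6] not in toy_cdbg and seq[8:13] not in toy_cdbg

    def test_boundary_run_covers_whole_sequence(self, toy_cdbg):
        runs = find_common_runs("AAAAACCCCC", toy_cdbg)
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end) == (0, 6)

    def test_no_shared_kmers_no_runs(self, toy_cdbg):
        assert find_common_runs("GTGTGTGTGT", toy_cdbg) == []

    def test_sequence_shorter_than_k(self, toy_cdbg):
        assert find_common_runs("AAA", toy_cdbg) == []

    def test_non_acgt_breaks_runs(self, toy_cdbg):
        # the N invalidates windows covering it, splitting the match
        runs = find_common_runs("AAAAACNCCCCC", toy_cdbg)
        assert len(runs) == 2


class TestExtractDfks:
    def test_overhang_one(self, toy_cdbg):
        dfks, report = extract_dfks([("d", "GGAAAAACCCCCTT")], toy_cdbg, 1)
        assert dfks.kmers == {"GAAAA", "AGGGG"}  # canonical("CCCCT") == "AGGGG"
        assert report.dfk_count == 2
        assert report.run_count == 1
        assert report.n_k == toy_cdbg.n_kmers

    def test_overhang_two_adds_next_flanks(self, toy_cdbg):
        dfks, report = extract_dfks([("d", "GGAAAAACCCCCTT")], toy_cdbg, 2)
        assert dfks.kmers == {"GAAAA", "AGGGG", "GGAAA", "AAGGG"}
        assert report.dfk_count == 4

    def test_empty_dlist(self, toy_cdbg):
        dfks, report = extract_dfks([], toy_cdbg, 1)
        assert len(dfks) == 0 and report.dfk_count == 0 and report.run_count == 0

    def test_dlist_equal_to_targets_yields_nothing(self, toy_cdbg):
        dfks, _ = extract_dfks([("t", "AAAAACCCCC")], toy_cdbg, 1)
        assert len(dfks) == 0

    def test_overhang_below_one_rejected(self, toy_cdbg):
        with pytest.raises(ValueError):
            extract_dfks([("d", "GGAAAAACCCCCTT")], toy_cdbg, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        targets, dlist = oracles.random_instance(rng, k=5, with_n=True)
        cdbg = CdBG.build(targets, 5)
        for h in (1, 2):
            dfks, _ = extract_dfks(dlist, cdbg, h)
            assert dfks.kmers == oracles.oracle_dfks(dlist, targets, 5, h)

    @pytest.mark.parametrize("seed", range(20))
    def test_invariants_on_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        targets, dlist = oracles.random_instance(rng, k=5)
        cdbg = CdBG.build(targets, 5)
        prev = None
        for h in (1, 2, 3):
            dfks, report = extract_dfks(dlist, cdbg, h)
            # disjointness from the graph
            assert all(km not in cdbg for km in dfks)
            # report bounds
            assert report.dfk_count == len(dfks) <= report.m_k
            assert report.dfk_count <= 2 * h * report.run_count
            # monotone in the overhang
            if prev is not None:
                assert prev <= dfks.kmers
            prev = dfks.kmers
            # idempotence
            again, _ = extract_dfks(dlist, cdbg, h)
            assert again.kmers == dfks.kmers


def _side_has_continuation(cdbg, terminal_kmer, direction):
    """Whether a unitig end has at least one in-graph extension."""
    if direction == "right":
        cands = [terminal_kmer[1:] + c for c in "ACGT"]
    else:
        cands = [c + terminal_kmer[:-1] for c in "ACGT"]
    return any(canonical(c) in cdbg for c in cands)


class TestPerUnitigFlankCapacity:
    """Worst-case DFK load on a single unitig.

    When both sides of a unitig retain an in-graph continuation (the generic
    branch-terminated case), each side admits at most |alphabet|-1 = 3 DFKs,
    for a total of 6.  A free end (tip) admits all 4 extensions, so an
    isolated-k-mer unitig can carry up to 8.
    """

    # single-k-mer unitig ACGGT, branch-terminated on both sides
    BRANCH_TARGETS = ["AACGGTA", "TCGGT", "ACGGA"]
    BRANCH_DLIST = [(f"d{x}{y}", x + "ACGGT" + y) for x, y in zip("CGT", "CGT")]

    def test_enumeration(self):
        assert per_side_flank_capacity(require_graph_continuation=True) == 3
        assert per_side_flank_capacity(require_graph_continuation=False) == 4

    def test_branch_terminated_worst_case_attains_six(self):
        cdbg = CdBG.build(self.BRANCH_TARGETS, 5)
        dfks, _ = extract_dfks(self.BRANCH_DLIST, cdbg, 1)
        attr = attribute_dfks_to_unitigs(dfks, cdbg, self.BRANCH_DLIST)
        assert max(len(v) for v in attr.values()) == 6

    def test_tip_worst_case_attains_eight(self):
        cdbg = CdBG.build(["ACGGT"], 5)
        dlist = [(f"t{x}{y}", x + "ACGGT" + y) for x in "ACGT" for y in "ACGT"]
        dfks, _ = extract_dfks(dlist, cdbg, 1)
        attr = attribute_dfks_to_unitigs(dfks, cdbg, dlist)
        assert max(len(v) for v in attr.values()) == 8

    @pytest.mark.parametrize("seed", range(15))
    def test_random_instances_respect_per_vertex_capacities(self, seed):
        """The flank capacity is a per-vertex bound: each anchor k-mer admits
        at most 3 DFKs on a side with an in-graph continuation, 4 on a free
        side.  (A multi-k-mer unitig can anchor flanks at every vertex, so no
        fixed per-unitig constant exists.)"""
        rng = np.random.default_rng(2000 + seed)
        targets, dlist = oracles.random_instance(rng, k=5)
        cdbg = CdBG.build(targets, 5)
        dfks, _ = extract_dfks(dlist, cdbg, 1)
        for anchor, kmers in attribute_dfks_to_anchors(dfks, cdbg, dlist).items():
            cap = sum(
                3 if _side_has_continuation(cdbg, anchor, side) else 4
                for side in ("left", "right")
            )
            assert len(kmers) <= cap
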