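import numpy as np
import pytest

from nacquant import (
    ClassifiedUmi,
    CountMatrix,
    TranscriptRecord,
    UmiRecord,
    build_index,
    build_reference_index,
    classify_targets,
    collapse_umis,
    count_matrices,
    sum_matrices,
    tcc_matrix,
)
from nacquant.errors import ValidationError


@pytest.fixture(scope="module")
def nac_index(toy_locus):
    genome = {toy_locus["genome"].name: toy_locus["genome"]}
    return build_reference_index(genome, [toy_locus["gene"]], 7, mode="nac", dlist=None)


@pytest.fixture(scope="module")
def two_gene_index():
    recs = [
        TranscriptRecord("t1", "g1", "AAAAACCCCCAAAAA", "mature"),
        TranscriptRecord("t2", "g2", "GTGTGAGAGAGTGTG", "mature"),
    ]
    return build_index(recs, 5)


class TestCollapse:
    def test_intersection_of_ecs(self, two_gene_index):
        idx = two_gene_index
        ec_both = idx.get_ec({0, 1})
        ec_t0 = idx.get_ec({0})
        records = [UmiRecord("bc", "u", ec_both), UmiRecord("bc", "u", ec_t0)]
        out = collapse_umis(records, idx)
        assert len(out) == 1
        assert out[0].targets == {0}

    def test_single_record_passes_through(self, two_gene_index):
        idx = two_gene_index
        out = collapse_umis([UmiRecord("bc", "u", idx.get_ec({1}))], idx)
        assert len(out) == 1 and out[0].targets == {1}

    def test_disjoint_ecs_drop_the_umi(self, two_gene_index):
        idx = two_gene_index
        records = [
            UmiRecord("bc", "u", idx.get_ec({0})),
            UmiRecord("bc", "u", idx.get_ec({1})),
        ]
        assert collapse_umis(records, idx) == []

    def test_dlist_pseudotarget_stripped(self, two_gene_index):
        idx = two_gene_index
        ec = idx.get_ec({0, idx.dlist_target_id})
        out = collapse_umis([UmiRecord("bc", "u", ec)], idx)
        assert len(out) == 1 and out[0].targets == {0}
        # a pure D-list EC yields nothing quantifiable
        pure = idx.get_ec({idx.dlist_target_id})
        assert collapse_umis([UmiRecord("bc", "u2", pure)], idx) == []


class TestClassification:
    def test_mature_only_is_M(self, nac_index):
        tid = nac_index.target_names.index("g1.t1")
        genes, status = classify_targets(frozenset({tid}), nac_index)
        assert genes == {"g1"} and status == "M"

    def test_nascent_only_is_N(self, nac_index):
        tid = nac_index.target_names.index("g1-I")
        genes, status = classify_targets(frozenset({tid}), nac_index)
        assert genes == {"g1"} and status == "N"

    def test_both_statuses_is_A(self, nac_index):
        ids = frozenset(
            {nac_index.target_names.index("g1.t1"), nac_index.target_names.index("g1-I")}
        )
        genes, status = classify_targets(ids, nac_index)
        assert genes == {"g1"} and status == "A"

    def test_multi_gene_has_no_single_status(self, two_gene_index):
        genes, status = classify_targets(frozenset({0, 1}), two_gene_index)
        assert genes == {"g1", "g2"} and status is None

    def test_empty_set_rejected(self, nac_index):
        with pytest.raises(ValidationError):
            classify_targets(frozenset(), nac_index)


class TestCountMatrices:
    def test_single_gene_umis_accumulate(self, two_gene_index):
        idx = two_gene_index
        classified = [
            ClassifiedUmi("bc1", f"u{i}", frozenset({0}), frozenset({"g1"}), "M")
            for i in range(3)
        ]
        mats = count_matrices(classified, idx)
        assert mats["M"].values[0, mats["M"].genes.index("g1")] == 3
        assert mats["N"].values.sum() == 0 and mats["A"].values.sum() == 0

    def test_multimapping_splits_uniformly(self, two_gene_index):
        idx = two_gene_index
        umi = ClassifiedUmi("bc", "u", frozenset({0, 1}), frozenset({"g1", "g2"}), None)
        mats = count_matrices([umi], idx, multimapping=True)
        m = mats["M"]
        assert m.values[0, m.genes.index("g1")] == pytest.approx(0.5)
        assert m.values[0, m.genes.index("g2")] == pytest.approx(0.5)

    def test_multimapping_off_discards_multi_gene_umis(self, two_gene_index):
        umi = ClassifiedUmi("bc", "u", frozenset({0, 1}), frozenset({"g1", "g2"}), None)
        mats = count_matrices([umi], two_gene_index, multimapping=False)
        assert all(m.values.sum() == 0 for m in mats.values())

    def test_umi_conservation(self, two_gene_index):
        idx = two_gene_index
        rng = np.random.default_rng(3)
        classified = []
        n_single = n_multi = 0
        for i in range(60):
            if rng.random() < 0.3:
                classified.append(
                    ClassifiedUmi("bc", f"u{i}", frozenset({0, 1}), frozenset({"g1", "g2"}), None)
                )
                n_multi += 1
            else:
                t = int(rng.integers(2))
                classified.append(
                    ClassifiedUmi("bc", f"u{i}", frozenset({t}), frozenset({f"g{t+1}"}), "M")
                )
                n_single += 1
        mats = count_matrices(classified, idx, multimapping=True)
        total = sum(m.values.sum() for m in mats.values())
        assert total == pytest.approx(n_single + n_multi)
        mats_off = count_matrices(classified, idx, multimapping=False)
        assert sum(m.values.sum() for m in mats_off.values()) == pytest.approx(n_single)


class TestSumModes:
    def _mats(self):
        barcodes, genes = ["b1"], ["g1"]
        n = CountMatrix(np.array([[2.0]]), barcodes, genes)
        m = CountMatrix(np.array([[3.0]]), barcodes, genes)
        a = CountMatrix(np.array([[1.0]]), barcodes, genes)
        return n, m, a

    def test_arithmetic(self):
        n, m, a = self._mats()
        assert sum_matrices(n, m, a, "cell").values[0, 0] == 4
        assert sum_matrices(n, m, a, "nucleus").values[0, 0] == 3
        assert sum_matrices(n, m, a, "total").values[0, 0] == 6

    def test_cell_plus_nucleus_minus_a_equals_total(self):
        rng = np.random.default_rng(11)
        barcodes = [f"b{i}" for i in range(4)]
        genes = [f"g{j}" for j in range(6)]
        n, m, a = (
            CountMatrix(rng.integers(0, 5, (4, 6)).astype(float), barcodes, genes)
            for _ in range(3)
        )
        cell = sum_matrices(n, m, a, "cell")
        nuc = sum_matrices(n, m, a, "nucleus")
        tot = sum_matrices(n, m, a, "total")
        np.testing.assert_allclose(cell.values + nuc.values - a.values, tot.values)

    def test_zero_n_makes_cell_equal_total(self):
        n, m, a = self._mats()
        n = CountMatrix(np.zeros((1, 1)), n.barcodes, n.genes)
        assert (
            sum_matrices(n, m, a, "cell").values == sum_matrices(n, m, a, "total").values
        ).all()

    def test_shape_mismatch_rejected(self):
        n, m, a = self._mats()
        bad = CountMatrix(np.zeros((2, 1)), ["b1", "b2"], ["g1"])
        with pytest.raises(ValidationError):
            sum_matrices(bad, m, a, "cell")

    def test_unknown_mode_rejected(self):
        n, m, a = self._mats()
        with pytest.raises(ValidationError):
            sum_matrices(n, m, a, "bulk")


class TestTcc:
    def test_counts_per_ec(self, two_gene_index):
        classified = [
            ClassifiedUmi("bc", "u1", frozenset({0}), frozenset({"g1"}), "M"),
            ClassifiedUmi("bc", "u2", frozenset({0}), frozenset({"g1"}), "M"),
            ClassifiedUmi("bc", "u3", frozenset({0, 1}), frozenset({"g1", "g2"}), None),
        ]
        tcc = tcc_matrix(classified, two_gene_index)
        assert tcc.ec_targets == [("t1",), ("t1", "t2")]
        assert tcc.values[:, 0].tolist() == [2.0, 1.0]

    def test_empty_input(self, two_gene_index):
        tcc = tcc_matrix([], two_gene_index)
        assert tcc.values.size == 0 and tcc.ec_targets == []


class TestMatrixIO:
    def test_mtx_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        mat = CountMatrix(
            rng.integers(0, 4, (3, 5)).astype(float),
            ["b1", "b2", "b3"],
            [f"g{j}" for j in range(5)],
        )
        mat.to_mtx(tmp_path / "m")
        back = CountMatrix.from_mtx(tmp_path / "m")
        np.testing.assert_allclose(back.values, mat.values)
        assert back.barcodes == mat.barcodes and back.genes == mat.genes

    def test_align_to_fills_missing_with_zeros(self):
        mat = CountMatrix(np.array([[1.0, 2.0]]), ["b1"], ["g1", "g2"])
        out = mat.align_to(["b2", "b1"], ["g2", "g3"])
        np.testing.assert_allclose(out.values, [[0, 0], [2, 0]])
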