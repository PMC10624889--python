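"""Clone-table parsing, chain/isotype assignment and diversity metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoprog.repertoire import (
    Chain,
    CloneRecord,
    CloneTable,
    CloneTableFormatError,
    Isotype,
    MetricScope,
    Receptor,
    assign_chain,
    assign_isotype,
    compute_all_scopes,
    compute_metrics,
    merge_duplicate_clones,
    read_clone_table,
)

from conftest import make_clone, make_table

TSV_HEADER = "cloneCount\tnSeqCDR3\tallVHitsWithScore\tallDHitsWithScore\tallJHitsWithScore\tallCHitsWithScore\n"


def write_tsv(tmp_path, rows, header=TSV_HEADER):
    path = tmp_path / "sample.tsv"
    path.write_text(header + "".join(rows))
    return path


class TestReadCloneTable:
    def test_valid_rows_ingested(self, tmp_path):
        rows = [
            "120.0\tACGTACGT\tIGKV1-5*00(900)\t\tIGKJ2*00(500)\t\n",
            "30.0\tACGTACGA\tIGHV3-23*00(800)\tIGHD3-10*00(100)\tIGHJ4*00(700)\tIGHG1*00(200)\n",
            "5.0\tTTTTACGT\tTRBV5-1*00(600)\t\tTRBJ2-5*00(300)\t\n",
        ]
        table = read_clone_table(write_tsv(tmp_path, rows), total_mapped_reads=1000)
        assert len(table.clones) == 3
        assert table.clones[0].read_count == 120
        assert table.clones[1].c_hits == ["IGHG1"]

    def test_zero_count_row_dropped(self, tmp_path):
        rows = ["0\tACGTACGT\tIGKV1-5\t\tIGKJ2\t\n", "7\tACGTACGA\tIGKV1-5\t\tIGKJ2\t\n"]
        table = read_clone_table(write_tsv(tmp_path, rows), total_mapped_reads=1000)
        assert [c.read_count for c in table.clones] == [7]

    def test_multi_hit_column_split(self, tmp_path):
        rows = ["9\tACGTACGT\tTRAV17*00(100),TRBV5*00(90)\t\tTRAJ50*00(80)\t\n"]
        table = read_clone_table(write_tsv(tmp_path, rows), total_mapped_reads=1000)
        assert table.clones[0].v_hits == ["TRAV17", "TRBV5"]

    def test_missing_column_names_offender(self, tmp_path):
        header = "cloneCount\tallVHitsWithScore\tallJHitsWithScore\n"
        with pytest.raises(CloneTableFormatError, match="nSeqCDR3"):
            read_clone_table(write_tsv(tmp_path, ["1\tIGKV1-5\tIGKJ2\n"], header), 1000)

    def test_unparseable_count_reports_line(self, tmp_path):
        rows = ["12\tACGTACGT\tIGKV1-5\t\tIGKJ2\t\n", "oops\tACGTACGA\tIGKV1-5\t\tIGKJ2\t\n"]
        with pytest.raises(CloneTableFormatError, match="line 3"):
            read_clone_table(write_tsv(tmp_path, rows), 1000)


class TestAssignChain:
    @pytest.mark.parametrize(
        "v, j, chain, receptor",
        [
            # concordant genes
            (["IGKV1-5"], ["IGKJ2"], Chain.IGK, Receptor.BCR),
            # ambiguous V resolved by a univocal compatible J
            (["TRAV17", "TRBV5"], ["TRAJ50"], Chain.TRA, Receptor.TCR),
            # irreconcilable V and J: chain missing, receptor family kept
            (["TRAV24"], ["TRBJ2-5"], Chain.MISSING, Receptor.TCR),
            # ambiguity in both slots, no unique resolution
            (["TRAV17", "TRBV5"], ["TRAJ50", "TRBJ2-5"], Chain.MISSING, Receptor.TCR),
            # cross-family conflict
            (["IGKV1-5"], ["TRAJ50"], Chain.MISSING, Receptor.UNDETERMINED),
        ],
    )
    def test_heuristic(self, v, j, chain, receptor):
        clone = CloneRecord("ACGTACGT", 1, v_hits=list(v), j_hits=list(j))
        assign_chain(clone)
        assert clone.chain is chain
        assert clone.receptor is receptor

    def test_no_gene_hits_excluded_everywhere(self):
        clone = CloneRecord("ACGTACGT", 5)
        assign_chain(clone)
        assert clone.receptor is Receptor.UNDETERMINED
        table = CloneTable("s", [clone], 100)
        assert compute_metrics(table, MetricScope("global_BCR")).n_clones == 0
        assert compute_metrics(table, MetricScope("global_TCR")).n_clones == 0

    def test_missing_chain_clone_kept_in_global_scope(self):
        clone = CloneRecord("ACGTACGT", 4, v_hits=["TRAV24"], j_hits=["TRBJ2-5"])
        assign_chain(clone)
        table = CloneTable("s", [clone], 100)
        assert compute_metrics(table, MetricScope("global_TCR")).n_clones == 1
        for chain in ("TRA", "TRB"):
            assert compute_metrics(table, MetricScope("chain", chain)).n_clones == 0


class TestAssignIsotype:
    @pytest.mark.parametrize(
        "chain, c_hits, expected",
        [
            ("IGH", ["IGHG1"], Isotype.IGG),
            ("IGH", ["IGHA2"], Isotype.IGA),
            ("IGH", ["IGHM"], Isotype.IGM),
            ("IGH", [], Isotype.UNDETERMINED),
            ("IGH", ["IGHG1", "IGHA1"], Isotype.UNDETERMINED),
            ("IGH", ["IGHG1", "IGHG3"], Isotype.IGG),
            ("IGK", ["IGKC"], Isotype.NOT_APPLICABLE),
        ],
    )
    def test_isotype_from_constant_region(self, chain, c_hits, expected):
        assert make_clone(1, chain=chain, c_hits=c_hits).isotype is expected


class TestMergeDuplicates:
    def test_same_cdr3_same_chain_merged(self):
        a = make_clone(3, "IGK", cdr3="ACGTACGTACGT")
        b = make_clone(2, "IGK", cdr3="ACGTACGTACGT")
        merged = merge_duplicate_clones(CloneTable("s", [a, b], 100))
        assert len(merged.clones) == 1
        assert merged.clones[0].read_count == 5

    def test_same_cdr3_other_chain_distinct(self):
        a = make_clone(3, "IGK", cdr3="ACGTACGTACGT")
        b = make_clone(2, "TRA", cdr3="ACGTACGTACGT")
        merged = merge_duplicate_clones(CloneTable("s", [a, b], 100))
        assert len(merged.clones) == 2


def gini_pairwise_oracle(counts):
    """O(n^2) relative mean absolute difference / 2."""
    x = np.asarray(counts, dtype=float)
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean()))


class TestComputeMetrics:
    def test_single_clone_edge_rules(self):
        m = compute_metrics(make_table([17]), MetricScope("chain", "IGK"))
        assert m.gini == 0.0
        assert m.gini_simpson == 0.0
        assert m.evenness is None
        assert m.second_clone_prop is None
        assert m.top_clone_prop == 1.0

    def test_two_clone_worked_example(self):
        m = compute_metrics(make_table([3, 1]), MetricScope("chain", "IGK"))
        assert m.top_clone_prop == pytest.approx(0.75)
        assert m.second_clone_prop == pytest.approx(0.25)
        assert m.gini_simpson == pytest.approx(0.375)
        assert m.gini == pytest.approx(0.25)
        assert m.evenness == pytest.approx(0.8112781244591328, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 5, 8])
    def test_uniform_counts(self, k):
        m = compute_metrics(make_table([6] * k), MetricScope("chain", "IGK"))
        assert m.evenness == pytest.approx(1.0)
        assert m.top_clone_prop == pytest.approx(1.0 / k)
        assert m.gini == pytest.approx(0.0)

    def test_normalization_factor(self):
        table = make_table([600, 400], total_mapped_reads=1000)
        m = compute_metrics(table, MetricScope("chain", "IGK"))
        assert m.n_reads_normalized == pytest.approx(1000.0)

    def test_empty_scope(self):
        m = compute_metrics(make_table([3, 1]), MetricScope("chain", "TRB"))
        assert m.n_clones == 0
        assert m.n_reads_normalized == 0.0
        assert m.gini is None and m.cdr3_length_mean is None

    def test_cdr3_length_unweighted_mean(self):
        a = make_clone(100, "IGK", cdr3="A" * 10 + "CG")  # len 12
        b = make_clone(1, "IGK", cdr3="A" * 22 + "CG")  # len 24
        table = CloneTable("s", [a, b], 100)
        m = compute_metrics(table, MetricScope("chain", "IGK"))
        assert m.cdr3_length_mean == pytest.approx(18.0)

    @given(st.lists(st.integers(min_value=1, max_value=10), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_gini_matches_pairwise_oracle(self, counts):
        m = compute_metrics(make_table(counts), MetricScope("chain", "IGK"))
        assert m.gini == pytest.approx(gini_pairwise_oracle(counts), abs=1e-12)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_evenness_bounds_and_permutation_invariance(self, counts):
        m = compute_metrics(make_table(counts), MetricScope("chain", "IGK"))
        assert 0.0 < m.evenness <= 1.0 + 1e-12
        if len(set(counts)) == 1:
            assert m.evenness == pytest.approx(1.0)
        perm = list(reversed(counts))
        mp = compute_metrics(make_table(perm), MetricScope("chain", "IGK"))
        for attr in ("gini", "gini_simpson", "evenness", "top_clone_prop"):
            assert getattr(m, attr) == pytest.approx(getattr(mp, attr))

    @given(st.lists(st.integers(min_value=2, max_value=30), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_concentration_monotonicity(self, counts):
        """Moving a read from the smallest to the largest clone concentrates
        the distribution: Gini and top proportion cannot fall, evenness
        cannot rise."""
        before = compute_metrics(make_table(counts), MetricScope("chain", "IGK"))
        shifted = sorted(counts)
        shifted[0] -= 1
        shifted[-1] += 1
        if shifted[0] < 1:
            return
        after = compute_metrics(make_table(shifted), MetricScope("chain", "IGK"))
        assert after.gini >= before.gini - 1e-12
        assert after.top_clone_prop >= before.top_clone_prop - 1e-12
        assert after.evenness <= before.evenness + 1e-12


class TestComputeAllScopes:
    def test_single_family_table(self):
        results = compute_all_scopes(make_table([5, 3], chain="IGK"))
        tcr = results[MetricScope("global_TCR")]
        assert tcr.n_clones == 0 and tcr.n_reads_normalized == 0.0
        bcr = results[MetricScope("global_BCR")]
        assert bcr.n_clones == 2

    def test_global_additivity_over_chains(self):
        clones = [make_clone(5, "TRA", cdr3="ACGT" * 5), make_clone(3, "TRB", cdr3="AC" * 6)]
        table = CloneTable("s", clones, 1000)
        results = compute_all_scopes(table)
        assert results[MetricScope("global_TCR")].n_clones == 2
        total = sum(
            results[MetricScope("chain", c)].n_reads_normalized
            for c in ("TRA", "TRB", "TRG", "TRD")
        )
        assert total == pytest.approx(
            results[MetricScope("global_TCR")].n_reads_normalized, abs=1e-9
        )

    def test_scope_count_and_order(self):
        results = compute_all_scopes(make_table([2]))
        labels = [s.label for s in results]
        assert labels[:2] == ["BCR", "TCR"]
        assert len(labels) == 14  # 2 globals + 7 chains + 5 isotypes
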