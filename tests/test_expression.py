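import numpy as np
import pandas as pd
import pytest

from famscan.expression import (
    CountMatrix,
    QpcrMeasurement,
    ddct,
    ddct_table,
    expression_sets,
    heatmap_matrix,
    match_orthologs,
    rpkm,
)
from famscan.io_formats import SequenceRecord
from famscan.synthetic_data import gen_diverged_pair

from conftest import random_dna


def count_matrix(counts, lengths, libs):
    return CountMatrix(
        pd.DataFrame(counts),
        pd.Series(lengths),
        pd.Series(libs),
    )


class TestRpkm:
    def test_closed_form(self):
        cm = count_matrix({"s": {"g": 10}}, {"g": 1000}, {"s": 1e6})
        assert rpkm(cm).at["g", "s"] == 10.0

    def test_zero_counts_give_zero(self):
        cm = count_matrix({"s": {"g": 0}}, {"g": 500}, {"s": 1e6})
        assert rpkm(cm).at["g", "s"] == 0.0

    def test_scale_invariance(self):
        cm1 = count_matrix({"s": {"g": 7}}, {"g": 800}, {"s": 1e6})
        cm2 = count_matrix({"s": {"g": 14}}, {"g": 800}, {"s": 2e6})
        assert rpkm(cm1).at["g", "s"] == rpkm(cm2).at["g", "s"]

    def test_linearity_in_counts(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(6, 3)),
            index=[f"g{i}" for i in range(6)],
            columns=list("abc"),
        )
        lengths = pd.Series(rng.integers(200, 5000, size=6), index=counts.index)
        libs = pd.Series([1e6, 2e6, 5e5], index=counts.columns)
        r1 = rpkm(CountMatrix(counts, lengths, libs))
        r3 = rpkm(CountMatrix(counts * 3, lengths, libs))
        assert np.allclose(r3.to_numpy(), 3 * r1.to_numpy())

    def test_zero_library_size_rejected(self):
        cm = count_matrix({"s": {"g": 0}}, {"g": 500}, {"s": 0})
        with pytest.raises(ValueError, match="zero library size"):
            rpkm(cm)

    def test_library_size_below_column_sum_rejected(self):
        with pytest.raises(ValueError, match="library size below"):
            count_matrix({"s": {"g": 100}}, {"g": 500}, {"s": 10})


class TestHeatmapMatrix:
    def test_identical_rows_end_up_adjacent(self):
        expr = pd.DataFrame(
            {"s1": [5.0, 100.0, 5.0], "s2": [1.0, 50.0, 1.0]},
            index=["gA", "gFar", "gB"],
        )
        layout = heatmap_matrix(expr)
        rows = layout.row_order
        assert abs(rows.index("gA") - rows.index("gB")) == 1

    def test_pseudocount_maps_zero_to_zero(self):
        expr = pd.DataFrame({"s1": [0.0], "s2": [3.0]}, index=["g"])
        layout = heatmap_matrix(expr, pseudo=1.0)
        assert layout.log_matrix.at["g", "s1"] == 0.0
        assert layout.log_matrix.at["g", "s2"] == 2.0

    def test_deterministic_across_runs(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 50, size=(8, 4)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(4)],
        )
        a, b = heatmap_matrix(expr), heatmap_matrix(expr)
        assert a.row_order == b.row_order and a.col_order == b.col_order
        assert a.log_matrix.equals(b.log_matrix)

    def test_single_gene_is_trivial(self):
        layout = heatmap_matrix(pd.DataFrame({"s1": [2.0], "s2": [4.0]}, index=["g"]))
        assert layout.row_order == ["g"]


class TestExpressionSets:
    GROUPS = {"s1": "root", "s2": "root", "s3": "leaf", "s4": "fruit"}

    def test_planted_memberships_recovered(self):
        expr = pd.DataFrame(
            {
                "s1": [5.0, 0.0, 2.0],
                "s2": [0.0, 0.0, 0.0],
                "s3": [3.0, 0.0, 0.0],
                "s4": [9.0, 0.5, 0.0],
            },
            index=["everywhere", "nowhere", "root_only"],
        )
        regions = expression_sets(expr, self.GROUPS, threshold=1.0)
        assert regions[frozenset({"root", "leaf", "fruit"})] == {"everywhere"}
        assert regions[frozenset({"root"})] == {"root_only"}
        assert "nowhere" not in {g for s in regions.values() for g in s}

    def test_regions_partition_expressed_genes(self, rng):
        expr = pd.DataFrame(
            rng.uniform(0, 3, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=list(self.GROUPS),
        )
        regions = expression_sets(expr, self.GROUPS)
        all_genes = [g for s in regions.values() for g in s]
        assert len(all_genes) == len(set(all_genes))
        expressed = set(expr.index[(expr >= 1.0).any(axis=1)])
        assert set(all_genes) == expressed

    def test_all_zero_matrix_gives_no_regions(self):
        expr = pd.DataFrame(0.0, index=["g1"], columns=list(self.GROUPS))
        assert expression_sets(expr, self.GROUPS) == {}

    def test_unknown_sample_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["g"])
        with pytest.raises(KeyError):
            expression_sets(expr, {"s1": "a", "ghost": "b"})


class TestMatchOrthologs:
    def test_identical_cds_matched(self):
        a, _, _ = gen_diverged_pair(60, 1.0, 0.0, seed=1)
        got = match_orthologs(
            [SequenceRecord("a1", a.sequence)], [SequenceRecord("b1", a.sequence)]
        )
        assert got == [("a1", "b1")]

    def test_identity_below_threshold_rejected(self, rng):
        seq = random_dna(rng, 300)
        chars = list(seq)
        for pos in rng.choice(300, size=9, replace=False):  # 97% identity
            chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
        assert (
            match_orthologs(
                [SequenceRecord("a1", seq)], [SequenceRecord("b1", "".join(chars))]
            )
            == []
        )

    def test_low_coverage_rejected(self, rng):
        shared = random_dna(rng, 120)
        a = SequenceRecord("a1", random_dna(rng, 80) + shared)
        b = SequenceRecord("b1", shared + random_dna(rng, 80))
        assert match_orthologs([a], [b]) == []

    def test_reciprocity_required(self):
        base, _, _ = gen_diverged_pair(60, 1.0, 0.0, seed=9)
        twin_a = SequenceRecord("a1", base.sequence)
        twin_a2 = SequenceRecord("a2", base.sequence)
        twin_b = SequenceRecord("b1", base.sequence)
        got = match_orthologs([twin_a, twin_a2], [twin_b])
        assert got == [("a1", "b1")]  # b1's best is a1 by id tie-break


class TestDdct:
    def test_calibrator_fold_is_one(self):
        m = QpcrMeasurement("s", [20, 20, 20], [18, 18, 18])
        assert ddct(m, m).fold == 1.0

    def test_one_cycle_doubling(self):
        sample = QpcrMeasurement("s", [19, 19, 19], [18, 18, 18])
        cal = QpcrMeasurement("c", [20, 20, 20], [18, 18, 18])
        assert ddct(sample, cal).fold == 2.0

    def test_worked_replicate_example(self):
        sample = QpcrMeasurement("s", [20, 20, 20], [18, 18, 18])
        cal = QpcrMeasurement("c", [21, 21, 21], [18, 18, 18])
        out = ddct(sample, cal)
        assert out.fold == 2.0 and out.sd == 0.0

    def test_fold_monotone_decreasing_in_target_ct(self):
        cal = QpcrMeasurement("c", [20.0], [18.0])
        folds = [
            ddct(QpcrMeasurement("s", [ct], [18.0]), cal).fold
            for ct in (18.0, 19.0, 20.0, 21.0)
        ]
        assert all(f > 0 for f in folds)
        assert all(a > b for a, b in zip(folds, folds[1:]))

    def test_missing_reference_replicates_rejected(self):
        with pytest.raises(ValueError, match="missing Ct"):
            QpcrMeasurement("s", [20.0], [])

    def test_tidy_table_interface(self):
        rows = []
        for sample, tgt in (("fruit6", 19.0), ("fruit16", 18.0)):
            rows += [{"sample": sample, "gene": "ABCG", "ct": tgt}] * 3
            rows += [{"sample": sample, "gene": "beta_tubulin", "ct": 17.0}] * 3
        table = ddct_table(pd.DataFrame(rows), "ABCG", "beta_tubulin", "fruit6")
        folds = dict(zip(table["sample"], table["fold"]))
        assert folds["fruit6"] == 1.0 and folds["fruit16"] == 2.0
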