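import math

import numpy as np
import pytest

from famscan.io_formats import SequenceRecord
from famscan.pairwise_align import CodonAlignment, codon_align
from famscan.selection_dating import (
    DatingParams,
    HomologyCriteria,
    SelectionCall,
    SelectionEstimate,
    classify_selection,
    duplication_time,
    find_paralog_pairs,
    load_reference_pairs,
    ng86,
    summarize_pairs,
)
from famscan.synthetic_data import gen_diverged_pair

from oracles import jc_distance_tolerance, ng86_bruteforce

NON_STOP = [
    c
    for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
]


def aln_from_codons(pairs):
    a = "".join(p[0] for p in pairs)
    b = "".join(p[1] for p in pairs)
    return CodonAlignment("a", "b", a, b, 0.0, 0.0)


class TestNg86:
    def test_identical_pair_all_zero(self):
        counts, est = ng86(aln_from_codons([("ATG", "ATG")] * 30))
        assert counts.sd == counts.nd == 0.0
        assert est.ka == est.ks == 0.0
        assert est.call is SelectionCall.UNDEFINED

    def test_two_codon_hand_enumeration(self):
        # TTT->TTC is synonymous (Phe); AAA's first position has a
        # stop-creating change (TAA) excluded from the site count.
        counts, est = ng86(aln_from_codons([("TTT", "TTC"), ("AAA", "AAA")]))
        assert counts.sd == 1.0 and counts.nd == 0.0
        assert counts.s_sites == pytest.approx(2.0 / 3.0)
        assert counts.n_sites == pytest.approx(6.0 - 2.0 / 3.0)
        assert est.ka == 0.0
        assert math.isinf(est.ks) and est.saturated  # 1 difference on 2/3 sites

    def test_gap_and_stop_codons_skipped(self):
        counts, _ = ng86(aln_from_codons([("ATG", "ATG"), ("---", "ATG"), ("TAA", "ATG"), ("ANG", "ATG")]))
        assert counts.compared_codons == 1

    def test_sites_sum_to_three_per_codon(self, rng):
        for _ in range(50):
            pairs = [
                (NON_STOP[int(rng.integers(61))], NON_STOP[int(rng.integers(61))])
                for _ in range(int(rng.integers(1, 20)))
            ]
            counts, _ = ng86(aln_from_codons(pairs))
            assert counts.s_sites + counts.n_sites == pytest.approx(
                3.0 * counts.compared_codons, abs=1e-9
            )

    def test_symmetry(self):
        a, b, _ = gen_diverged_pair(80, 0.7, 0.3, seed=4)
        fwd = ng86(codon_align(a, b))
        rev = ng86(codon_align(b, a))
        assert fwd[0].sd == rev[0].sd and fwd[0].nd == rev[0].nd
        assert fwd[1].ka == rev[1].ka and fwd[1].ks == rev[1].ks

    def test_matches_bruteforce_oracle_on_random_short_alignments(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 4))
            pairs = [
                (NON_STOP[int(rng.integers(61))], NON_STOP[int(rng.integers(61))])
                for _ in range(n)
            ]
            counts, est = ng86(aln_from_codons(pairs))
            want = ng86_bruteforce(pairs)
            assert counts.s_sites == pytest.approx(want["s_sites"], abs=1e-9)
            assert counts.sd == pytest.approx(want["sd"], abs=1e-9)
            assert counts.nd == pytest.approx(want["nd"], abs=1e-9)
            checks = (
                (est.ka, want["ka"], counts.nd / counts.n_sites),
                (est.ks, want["ks"], counts.sd / counts.s_sites),
            )
            for got_d, want_d, p in checks:
                if math.isinf(want_d):
                    assert math.isinf(got_d)
                else:
                    assert got_d == pytest.approx(want_d, abs=jc_distance_tolerance(p))

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError, match="no comparable codons"):
            ng86(aln_from_codons([("---", "ATG")]))


class TestClassification:
    @pytest.mark.parametrize(
        "omega,expected",
        [
            (1.06, SelectionCall.POSITIVE),
            (0.06, SelectionCall.PURIFYING),
            (1.57, SelectionCall.POSITIVE),
            (0.95, SelectionCall.PURIFYING),
        ],
    )
    def test_omega_thresholds(self, omega, expected):
        est = SelectionEstimate(ka=0.1, ks=0.1 / omega, omega=omega, call=SelectionCall.UNDEFINED)
        assert classify_selection(est) is expected

    def test_zero_divergence_is_undefined(self):
        est = SelectionEstimate(0.0, 0.0, None, SelectionCall.UNDEFINED)
        assert classify_selection(est) is SelectionCall.UNDEFINED

    def test_neutral_band(self):
        est = SelectionEstimate(0.101, 0.1, 1.01, SelectionCall.UNDEFINED)
        assert classify_selection(est, eps=0.05) is SelectionCall.NEUTRAL


class TestDating:
    def test_zero_ks_is_time_zero(self):
        assert duplication_time(0.0) == 0.0

    def test_default_clock_rate(self):
        assert duplication_time(0.21) == pytest.approx(15.09, abs=0.005)

    def test_linearity(self):
        assert duplication_time(0.5) == pytest.approx(2 * duplication_time(0.25))

    def test_custom_rate(self):
        assert duplication_time(0.2, DatingParams(1e-8)) == pytest.approx(10.0)

    def test_saturated_ks_propagates(self):
        assert math.isinf(duplication_time(math.inf))

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            duplication_time(-0.1)
        with pytest.raises(ValueError):
            DatingParams(0.0)


class TestParalogPairs:
    def test_exact_duplicates_retained_at_full_scores(self):
        a, _, _ = gen_diverged_pair(60, 0.5, 0.0, seed=1)
        recs = [
            SequenceRecord("g1", a.sequence),
            SequenceRecord("g2", a.sequence),
        ]
        (pair,) = find_paralog_pairs(recs)
        assert (pair.gene_a, pair.gene_b) == ("g1", "g2")
        assert pair.identity_pct == 100.0 and pair.coverage_pct == 100.0
        assert pair.t_mya == 0.0

    def test_low_identity_pair_excluded(self):
        a, _, _ = gen_diverged_pair(60, 1.0, 0.0, seed=2)
        b, _, _ = gen_diverged_pair(60, 1.0, 0.0, seed=3)  # unrelated
        assert find_paralog_pairs([a, SequenceRecord("other", b.sequence)]) == []

    def test_planted_three_copy_family_is_strongly_connected(self):
        anc, _, _ = gen_diverged_pair(80, 0.5, 0.0, seed=5)
        copies = []
        for i, seed in enumerate((10, 11, 12)):
            mutated, _, _ = gen_diverged_pair(80, 0.5, 0.0, seed=5)  # same ancestor
            copies.append(SequenceRecord(f"c{i}", mutated.sequence))
        pairs = find_paralog_pairs(copies)
        assert len(pairs) == 3
        assert all(p.component_size == 3 and p.strongly_connected for p in pairs)

    def test_single_edge_component_is_not_strong(self):
        a, _, _ = gen_diverged_pair(60, 0.5, 0.0, seed=6)
        pairs = find_paralog_pairs(
            [SequenceRecord("g1", a.sequence), SequenceRecord("g2", a.sequence)]
        )
        assert pairs[0].strongly_connected is False

    def test_inclusive_criteria_flag(self):
        a, _, _ = gen_diverged_pair(60, 0.5, 0.0, seed=7)
        recs = [SequenceRecord("g1", a.sequence), SequenceRecord("g2", a.sequence)]
        strict_100 = find_paralog_pairs(recs, HomologyCriteria(100.0, 100.0))
        inclusive_100 = find_paralog_pairs(recs, HomologyCriteria(100.0, 100.0, inclusive=True))
        assert strict_100 == [] and len(inclusive_100) == 1


class TestSummaries:
    def test_reference_table_summary(self):
        summary = summarize_pairs(load_reference_pairs())
        assert summary["n_pairs"] == 14
        assert round(summary["mean_omega"], 2) == 0.81
        assert summary["min_omega"] == 0.06 and summary["max_omega"] == 1.57
        assert summary["n_purifying"] == 11 and summary["n_positive"] == 3
        assert summary["n_intraspecies"] == 8

    def test_single_pair_table(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"gene_a": "CaABCG1", "gene_b": "CbABCG2", "omega": 0.5, "t_mya": 10.0}]
        )
        summary = summarize_pairs(df)
        assert summary["mean_omega"] == summary["min_omega"] == summary["max_omega"] == 0.5
        assert summary["n_intraspecies"] == 0

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            summarize_pairs(pd.DataFrame())
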