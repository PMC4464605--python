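import numpy as np
import pandas as pd
import pytest

from conftest import make_gene
from oracles import brute_force_bh, brute_force_exon_calls
from splicebench.annotation import GenomeAnnotation
from splicebench.evaluation import (
    CallerResult,
    CallSet,
    bh_adjust,
    call_from_exon_level,
    call_from_transcript_level,
    evaluate_calls,
    ma_statistics,
    two_group_count_test,
)
from splicebench.selection import CountsMatrix
from splicebench.simulate import TruthTable

SAMPLES = ["C1", "C2", "C3", "T1", "T2", "T3"]
GROUPS = {s: s[0] for s in SAMPLES}


def truth_from(counts_by_transcript):
    counts = pd.DataFrame(counts_by_transcript, index=SAMPLES).T
    return TruthTable.from_counts(counts, GROUPS)


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_step_up_example(self):
        # min over the tail of p*n/rank: every element collapses to 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_adjusted_dominates_raw_and_is_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert all(qi >= pi for qi, pi in zip(q, p))
        assert max(q) <= 1.0

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = np.round(rng.uniform(size=n), 4)
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])


class TestTranscriptLevelCalls:
    def make_result(self, scores):
        return CallerResult(
            level="transcript",
            scores=pd.Series(scores),
        )

    def test_threshold_is_inclusive_at_alpha(self):
        calls = call_from_transcript_level(self.make_result({"a": 0.05}))
        assert calls.called_transcripts == {"a"}

    def test_empty_result_gives_empty_callset(self):
        calls = call_from_transcript_level(self.make_result({}))
        assert calls.called_transcripts == set()

    def test_counts_just_over_threshold_excluded(self):
        calls = call_from_transcript_level(
            self.make_result({"a": 0.01, "b": 0.049, "c": 0.051})
        )
        assert calls.called_transcripts == {"a", "b"}

    def test_exon_level_input_is_a_usage_error(self):
        result = CallerResult(level="exon", scores=pd.Series({"g:0-1": 0.01}))
        with pytest.raises(ValueError, match="transcript-level"):
            call_from_transcript_level(result)


@pytest.fixture
def exon_annotation():
    # gA: shared bin 0-100 ({t1,t2}), specific bins 200-300 (t1), 400-500 (t2)
    # gB: single-isoform gene, everything specific
    gene_a = make_gene(
        "gA", {"t1": [(0, 100), (200, 300)], "t2": [(0, 100), (400, 500)]}
    )
    gene_b = make_gene("gB", {"t3": [(600, 700)]})
    return GenomeAnnotation(genes={"gA": gene_a, "gB": gene_b})


class TestExonLevelCalls:
    def test_significant_shared_bin_calls_no_transcript(self, exon_annotation):
        result = CallerResult(level="exon", scores=pd.Series({"gA:0-100": 0.001}))
        calls = call_from_exon_level(result, exon_annotation)
        assert calls.called_transcripts == set()

    def test_specific_bin_at_004_calls_its_transcript(self, exon_annotation):
        result = CallerResult(level="exon", scores=pd.Series({"gA:200-300": 0.04}))
        calls = call_from_exon_level(result, exon_annotation)
        assert calls.called_transcripts == {"t1"}

    def test_raw_pvalues_are_bh_adjusted_before_calling(self, exon_annotation):
        # raw 0.04 with 10 larger companions adjusts above 0.05 -> no call
        scores = {"gA:200-300": 0.04}
        scores.update({f"gB:{600 + i}-{600 + i + 1}": 0.9 for i in range(9)})
        # those gB ids are not real bins; use the real one plus synthetic gA ids
        result = CallerResult(
            level="exon",
            scores=pd.Series({"gA:200-300": 0.04, "gA:400-500": 0.9, "gA:0-100": 0.8}),
            adjusted=False,
        )
        calls = call_from_exon_level(result, exon_annotation)
        assert calls.called_transcripts == set()

    def test_unmappable_exon_id_is_a_consistency_error(self, exon_annotation):
        result = CallerResult(level="exon", scores=pd.Series({"nope:0-1": 0.01}))
        with pytest.raises(ValueError, match="absent from annotation"):
            call_from_exon_level(result, exon_annotation)

    def test_matches_brute_force_rule_on_random_fixture(self, toy_bundle):
        rng = np.random.default_rng(3)
        bin_ids = [b.bin_id for b in toy_bundle.annotation.bins()]
        adjusted = {b: float(rng.uniform()) ** 2 for b in bin_ids}
        result = CallerResult(
            level="exon", scores=pd.Series(adjusted), adjusted=True
        )
        calls = call_from_exon_level(result, toy_bundle.annotation)
        assert calls.called_transcripts == brute_force_exon_calls(
            toy_bundle.annotation, adjusted, 0.05
        )

    def test_invariant_to_row_order_permutation(self, toy_bundle):
        rng = np.random.default_rng(9)
        bin_ids = [b.bin_id for b in toy_bundle.annotation.bins()]
        scores = pd.Series(rng.uniform(size=len(bin_ids)) ** 2, index=bin_ids)
        shuffled = scores.sample(frac=1.0, random_state=5)
        a = call_from_exon_level(
            CallerResult(level="exon", scores=scores, adjusted=False),
            toy_bundle.annotation,
        )
        b = call_from_exon_level(
            CallerResult(level="exon", scores=shuffled, adjusted=False),
            toy_bundle.annotation,
        )
        assert a.called_transcripts == b.called_transcripts


class TestEvaluateCalls:
    def test_perfect_calls_score_full_detection_no_fp(self):
        truth = truth_from({"t1": [5, 5, 5, 20, 20, 20], "t2": [9, 9, 9, 3, 3, 3]})
        calls = CallSet({"t1", "t2"}, alpha=0.05)
        result = evaluate_calls(calls, truth)
        assert (result.tp, result.fp) == (2, 0)
        assert result.detection_pct == 100.0
        assert result.realized_fdr == 0.0

    def test_extra_call_counts_as_false_positive(self):
        truth = truth_from({"t1": [5, 5, 5, 20, 20, 20]})
        result = evaluate_calls(CallSet({"t1", "x"}, alpha=0.05), truth)
        assert (result.tp, result.fp) == (1, 1)
        assert result.realized_fdr == pytest.approx(0.5)

    def test_empty_callset_has_zero_fdr_denominator_guard(self):
        truth = truth_from({"t1": [5, 5, 5, 20, 20, 20]})
        result = evaluate_calls(CallSet(set(), alpha=0.05), truth)
        assert (result.tp, result.fp, result.realized_fdr) == (0, 0, 0.0)

    def test_random_call_sets_match_set_arithmetic_oracle(self):
        rng = np.random.default_rng(11)
        universe = [f"t{i}" for i in range(40)]
        truth = truth_from({t: list(rng.integers(1, 50, 6)) for t in universe[:15]})
        for _ in range(25):
            called = {t for t in universe if rng.random() < 0.4}
            result = evaluate_calls(CallSet(called, alpha=0.05), truth)
            expected_tp = len(called & set(universe[:15]))
            assert result.tp == expected_tp
            assert result.fp == len(called) - expected_tp
            assert result.detection_pct == pytest.approx(100 * expected_tp / 15)

    def test_empty_truth_rejected(self):
        empty = TruthTable.from_counts(pd.DataFrame(columns=SAMPLES), GROUPS)
        with pytest.raises(ValueError, match="empty"):
            evaluate_calls(CallSet({"a"}, alpha=0.05), empty)


class TestMAStatistics:
    def matrix(self, rows):
        values = pd.DataFrame(rows, index=SAMPLES).T
        return CountsMatrix(values, GROUPS)

    def test_identical_groups_have_zero_log2fc(self):
        stats = ma_statistics(self.matrix({"t1": [7, 7, 7, 7, 7, 7]}))
        assert stats.loc["t1", "avg_log2fc"] == pytest.approx(0.0)

    def test_doubling_approaches_log2fc_one_as_epsilon_vanishes(self):
        matrix = self.matrix({"t1": [100, 100, 100, 200, 200, 200]})
        fc = ma_statistics(matrix, epsilon=1e-9).loc["t1", "avg_log2fc"]
        assert fc == pytest.approx(1.0, abs=1e-6)

    def test_abundance_axis_is_log10_of_overall_mean(self):
        matrix = self.matrix({"t1": [10, 10, 10, 1000, 1000, 1000]})
        stats = ma_statistics(matrix, epsilon=0.5)
        assert stats.loc["t1", "avg_log10_count"] == pytest.approx(
            np.log10(505.5)
        )

    def test_spiked_two_fold_means_recover_log2fc_near_one(self):
        rng = np.random.default_rng(17)
        rows = {
            f"t{i}": np.concatenate(
                [rng.poisson(100, 3), rng.poisson(200, 3)]
            ).tolist()
            for i in range(30)
        }
        stats = ma_statistics(self.matrix(rows))
        assert stats["avg_log2fc"].mean() == pytest.approx(1.0, abs=0.1)

    def test_missing_group_is_a_usage_error(self):
        values = pd.DataFrame({"C1": [1], "C2": [2]}, index=["t1"])
        matrix = CountsMatrix(values, {"C1": "C", "C2": "C"})
        with pytest.raises(ValueError, match="both C and T"):
            ma_statistics(matrix)


def test_two_group_count_test_separates_planted_signal_from_null():
    rng = np.random.default_rng(23)
    null = {f"n{i}": rng.poisson(50, 6).tolist() for i in range(40)}
    signal = {f"s{i}": np.concatenate(
        [rng.poisson(100, 3), rng.poisson(400, 3)]
    ).tolist() for i in range(5)}
    counts = pd.DataFrame({**null, **signal}, index=SAMPLES).T
    result = two_group_count_test(counts, GROUPS)
    calls = call_from_transcript_level(result)
    assert {f"s{i}" for i in range(5)} <= calls.called_transcripts
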