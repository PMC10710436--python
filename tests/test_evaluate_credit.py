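import math

import edlib
import pytest

from phasebench.evaluate_credit import (QueryGraph, align_truth_to_query_graph,
                                        credit_segment,
                                        enumerate_local_phasings, f1_qscore,
                                        find_sync_points, select_phasing,
                                        summarize)
from phasebench.vcf_io import Variant, apply_variants

from .conftest import random_dna
from .oracles import brute_force_graph_distance


def _lev(a, b):
    return edlib.align(a, b)["editDistance"]


class TestGraphAlignment:
    def test_false_positive_skipped_free(self):
        window = "ACGTACGT"
        graph = QueryGraph(window, [Variant(3, "T", "G")])
        d, _ = align_truth_to_query_graph(window, graph)
        assert d == 0

    def test_exact_call_taken(self):
        window = "ACGTACGT"
        qv = [Variant(2, "G", "C"), Variant(5, "", "TT")]
        truth_seq = apply_variants(window, qv)
        d, _ = align_truth_to_query_graph(truth_seq, QueryGraph(window, qv))
        assert d == 0

    def test_partial_indel_length(self):
        # truth: 3-bp insertion; query called a 1-bp insertion there
        window = "ACGTACGT"
        truth_seq = apply_variants(window, [Variant(4, "", "GGG")])
        graph = QueryGraph(window, [Variant(4, "", "G")])
        d, _ = align_truth_to_query_graph(truth_seq, graph)
        assert d == 2

    def test_deletion_branch(self):
        window = "ACGTACGT"
        qv = [Variant(2, "GT", "")]
        truth_seq = apply_variants(window, qv)
        d, _ = align_truth_to_query_graph(truth_seq, QueryGraph(window, qv))
        assert d == 0

    def test_matches_subset_enumeration(self, rng):
        """Graph distance equals the minimum over all variant subsets."""
        for _ in range(40):
            window = random_dna(rng, 14)
            qv = []
            pos = 0
            while pos < len(window) - 2 and len(qv) < 3:
                pos += int(rng.integers(1, 5))
                if pos >= len(window) - 1:
                    break
                kind = rng.integers(0, 3)
                if kind == 0:
                    alt = "ACGT"[("ACGT".index(window[pos]) + 1) % 4]
                    qv.append(Variant(pos, window[pos], alt))
                    pos += 1
                elif kind == 1:
                    qv.append(Variant(pos, "", random_dna(rng, 2)))
                else:
                    end = min(pos + 2, len(window) - 1)
                    qv.append(Variant(pos, window[pos:end], ""))
                    pos = qv[-1].end
            truth_seq = apply_variants(
                window, [v for v in qv if rng.random() < 0.5])
            got, _ = align_truth_to_query_graph(truth_seq,
                                                QueryGraph(window, qv))
            want = brute_force_graph_distance(window, truth_seq, qv, _lev)
            assert got == want


class TestSelectPhasing:
    def test_parallel(self):
        assert select_phasing([[0, 5], [5, 0]]) == "X"

    def test_crossed(self):
        assert select_phasing([[5, 0], [0, 5]]) == "Y"

    def test_homozygous_tie_uncategorized(self):
        assert select_phasing([[2, 2], [2, 2]]) is None


class TestSyncPoints:
    def test_no_variants_every_base_syncs(self):
        window = "ACGTAC"
        d, path = align_truth_to_query_graph(window, QueryGraph(window, []))
        assert find_sync_points(path, [], []) == list(range(len(window)))

    def test_snp_base_excluded(self):
        window = "ACGTAC"
        qv = [Variant(3, "T", "G")]
        truth_seq = apply_variants(window, qv)
        d, path = align_truth_to_query_graph(truth_seq, QueryGraph(window, qv))
        assert find_sync_points(path, [], qv) == [0, 1, 2, 4, 5]

    def test_overlapping_deletions_no_internal_sync(self):
        window = "ACGTACGTAC"
        tv = [Variant(2, "GTAC", "")]
        qv = [Variant(4, "ACGT", "")]
        truth_seq = apply_variants(window, tv)
        d, path = align_truth_to_query_graph(truth_seq, QueryGraph(window, qv))
        syncs = find_sync_points(path, tv, qv)
        assert all(s < 2 or s >= 8 for s in syncs)


class TestCreditSegment:
    def test_printed_partial_fraction(self):
        """Edit distance reduced from 3 to 1: counted 2/3 TP + 1/3 FP."""
        window = "ACGTACGT"
        tv = [Variant(4, "", "GGG", 50.0)]
        qv = [Variant(4, "", "GG", 40.0)]
        recs = credit_segment(window, (0, 8), tv, qv, 0, 0, 0, 0)
        assert all(r.category == "PP" for r in recs)
        assert all(r.credit == pytest.approx(2 / 3) for r in recs)

    def test_exact_match_full_credit(self):
        window = "ACGTACGT"
        tv = [Variant(2, "GT", "", 50.0)]
        recs = credit_segment(window, (0, 8), tv, list(tv), 0, 0, 0, 0)
        assert all(r.category == "TP" and r.credit == 1.0 for r in recs)

    def test_unchanged_distance_is_fp_fn(self):
        window = "ACGTACGT"
        tv = [Variant(2, "G", "A", 50.0)]
        qv = [Variant(5, "C", "T", 50.0)]
        recs = credit_segment(window, (0, 8), tv, qv, 0, 0, 0, 0)
        by_role = {r.role: r for r in recs}
        assert by_role["truth"].category == "FN"
        assert by_role["query"].category == "FP"
        assert all(r.credit == 0.0 for r in recs)

    def test_worse_than_reference_clamped_to_fp(self):
        window = "ACGTACGT"
        qv = [Variant(2, "G", "A", 50.0)]
        recs = credit_segment(window, (0, 8), [], qv, 0, 0, 0, 0)
        assert recs[0].category == "FP" and recs[0].credit == 0.0


class TestSummarize:
    def _perfect(self):
        window = "ACGTACGT"
        tv = [Variant(2, "G", "C", 50.0)]
        return credit_segment(window, (0, 8), tv, list(tv), 0, 0, 0, 0)

    def test_perfect_scores_one(self):
        df = summarize(self._perfect())
        snp = df[df["class"] == "SNP"].iloc[0]
        assert snp.precision == snp.recall == snp.f1 == 1.0

    def test_f1_qscore_examples(self):
        assert f1_qscore(0.99) == pytest.approx(20.0)
        assert f1_qscore(1.0) == 100.0  # capped

    def test_single_partial_positive_propagates(self):
        window = "ACGTACGT"
        tv = [Variant(4, "", "GGG", 50.0)]
        qv = [Variant(4, "", "GG", 40.0)]
        df = summarize(credit_segment(window, (0, 8), tv, qv, 0, 0, 0, 0))
        row = df[df["class"] == "INDEL"].iloc[0]
        assert row.precision == pytest.approx(2 / 3)
        assert row.recall == pytest.approx(2 / 3)

    def test_homozygous_fp_counts_twice(self):
        window = "ACGTACGT"
        recs = []
        for hap in (0, 1):  # same FP variant evaluated on both haplotypes
            qv = [Variant(2, "G", "A", 50.0)]
            recs += credit_segment(window, (0, 8), [], qv, 0, 0, hap, hap)
        df = summarize(recs)
        assert df[df["class"] == "SNP"].iloc[0].fp_query == 2.0

    def test_threshold_sweep_monotone(self):
        window = "ACGTACGT"
        recs = credit_segment(window, (0, 8),
                              [Variant(2, "G", "C", 50.0)],
                              [Variant(2, "G", "C", 10.0)], 0, 0, 0, 0)
        recs += credit_segment(window, (0, 8),
                               [Variant(5, "C", "T", 50.0)],
                               [Variant(5, "C", "T", 30.0)], 1, 0, 0, 0)
        df = summarize(recs, [0.0, 20.0, 40.0])
        snp = df[df["class"] == "SNP"].sort_values("threshold")
        kept = (snp.tp_query + snp.fp_query).tolist()
        assert kept == sorted(kept, reverse=True)
        assert snp.iloc[0].recall == 1.0 and snp.iloc[2].recall == 0.0

    def test_conservation_per_variant(self):
        """TP + FP fractions of any query variant sum to one."""
        window = "ACGTACGT"
        for qv_alt in ("GG", "GGG"):
            recs = credit_segment(window, (0, 8),
                                  [Variant(4, "", "GGG", 50.0)],
                                  [Variant(4, "", qv_alt, 40.0)], 0, 0, 0, 0)
            for r in recs:
                assert 0.0 <= r.credit <= 1.0
                assert (r.credit + (1.0 - r.credit)) == 1.0


def test_five_het_variants_admit_32_phasings():
    vs = [Variant(i * 10, "A", "C") for i in range(5)]
    assignments = list(enumerate_local_phasings(vs))
    assert len(assignments) == 32
    # each assignment is a partition of the variants
    for hap0, hap1 in assignments:
        assert sorted(v.start for v in hap0 + hap1) == \
            [v.start for v in vs]
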