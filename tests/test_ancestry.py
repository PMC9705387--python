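"""Ancestry classification, recombinant detection and summary statistics."""

import warnings

import pytest

from subpaint import ancestry as an
from subpaint.alignio import AlignmentRecord, ContigSet
from subpaint.ancestry import AncestryCall, AncestryParams, DepthRecord

PARAMS = AncestryParams()


def rec(qid, qs, qe, rid="ref", idy=99.0):
    return AlignmentRecord(
        query_id=qid, query_start=qs, query_end=qe, ref_id=rid,
        ref_start=qs, ref_end=qe, strand="+",
        aligned_columns=qe - qs, identity_pct=idy,
    )


class TestCallContig:
    def test_dominant_side_wins(self):
        call = an.call_contig_ancestry(
            [rec("c", 0, 80_000)], [rec("c", 90_000, 95_000)], 100_000, PARAMS)
        assert call.category == "A_dominant"
        assert (call.bp_A, call.bp_B) == (80_000, 5_000)

    def test_balanced_tallies_are_equal(self):
        # near-identical region: both ancestors credited, |41000-39000|/80000
        # = 0.025 <= 0.10 and the 2 kb exclusive overhang is below the
        # recombinant run floor
        call = an.call_contig_ancestry(
            [rec("c", 0, 41_000, idy=97.0)], [rec("c", 0, 39_000, idy=97.0)],
            100_000, PARAMS)
        assert (call.bp_A, call.bp_B) == (41_000, 39_000)
        assert call.category == "equal"

    def test_no_alignment_is_unaligned(self):
        call = an.call_contig_ancestry([], [], 100_000, PARAMS, contig_id="c")
        assert call.category == "unaligned" and call.bp_A == call.bp_B == 0

    def test_sub_threshold_alignment_is_unaligned(self):
        call = an.call_contig_ancestry([rec("c", 0, 5_000)], [], 100_000, PARAMS)
        assert call.category == "unaligned"

    def test_mixed_contig_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple contigs"):
            an.call_contig_ancestry([rec("c1", 0, 10_000)], [rec("c2", 0, 10_000)],
                                    100_000, PARAMS)

    def test_competitive_credit_resolves_double_coverage(self):
        """A contig covered end to end by both ancestors is credited to the
        higher-identity side."""
        call = an.call_contig_ancestry(
            [rec("c", 0, 100_000, idy=100.0)],
            [rec("c", 0, 100_000, idy=94.3)],
            100_000, PARAMS)
        assert call.category == "A_dominant"
        assert call.bp_A == 100_000 and call.bp_B == 0

    def test_pure_contigs_recover_true_ancestor(self, dataset):
        calls = an.call_assembly(dataset.aln_a, dataset.aln_b, dataset.contigs)
        pure = [c for c in dataset.truth if not c.is_chimeric]
        acc = sum(
            1 for c in pure
            if calls[c.contig_id].category == c.dominant_ancestry + "_dominant"
        ) / len(pure)
        assert acc >= 0.95


class TestDetectRecombinant:
    def test_half_and_half_contig(self):
        is_rec, segs, bps = an.detect_recombinant(
            [rec("c", 0, 100_000)], [rec("c", 100_000, 200_000)], 200_000, PARAMS)
        assert is_rec
        assert len(bps) == 1 and abs(bps[0] - 100_000) <= PARAMS.window_bp // 2
        assert [s[2] for s in segs] == ["A", "B"]
        assert segs[0][0] == 0 and segs[-1][1] == 200_000

    def test_doubly_covered_contig_is_not_recombinant(self):
        """Equal-identity coverage by both ancestors leaves no exclusive
        runs, so nothing alternates."""
        is_rec, _, _ = an.detect_recombinant(
            [rec("c", 0, 200_000, idy=97.0)], [rec("c", 0, 200_000, idy=97.0)],
            200_000, PARAMS)
        assert not is_rec

    def test_short_foreign_segment_below_floor_ignored(self):
        is_rec, _, _ = an.detect_recombinant(
            [rec("c", 0, 195_000)], [rec("c", 195_000, 200_000)], 200_000, PARAMS)
        assert not is_rec

    def test_planted_chimeras_recovered(self, dataset):
        calls = an.call_assembly(dataset.aln_a, dataset.aln_b, dataset.contigs)
        from subpaint.synthdata import evaluate_recovery

        scores = evaluate_recovery(calls, dataset.truth)
        assert scores["chimera_sensitivity"] >= 0.90
        assert scores["chimera_fpr"] <= 0.05
        assert scores["breakpoint_mae"] <= 2_000


class TestDivergenceResponse:
    def test_recovery_improves_with_progenitor_divergence(self):
        """Ancestry accuracy and chimera sensitivity are non-decreasing in
        the simulated progenitor divergence: the closer the subgenomes, the
        harder they are to tell apart."""
        from subpaint import synthdata as sd

        acc, sens = [], []
        for d in (0.01, 0.03, 0.06, 0.10):
            p = sd.SimParams(seed=21, divergence=d, genome_length=500_000,
                             n_chromosome_segments=2, n_contigs=60,
                             contig_length=(120_000, 180_000),
                             chimera_fraction=0.3)
            ds = sd.simulate_dataset(p)
            calls = an.call_assembly(ds.aln_a, ds.aln_b, ds.contigs)
            scores = sd.evaluate_recovery(calls, ds.truth)
            acc.append(scores["pure_accuracy"])
            sens.append(scores["chimera_sensitivity"])
        assert acc == sorted(acc)
        assert sens == sorted(sens)
        assert acc[-1] >= 0.95 and sens[-1] >= 0.90


class TestDisambiguate:
    def _equal_call(self):
        return {"c": AncestryCall("c", 100_000, 40_000, 40_000, "equal")}

    def test_decisive_second_pass_reassigns(self):
        out = an.disambiguate_equal(
            self._equal_call(), [rec("c", 0, 30_000)], [rec("c", 50_000, 52_000)])
        assert out["c"].category == "A_dominant" and out["c"].disambiguated

    def test_still_balanced_second_pass_keeps_equal(self):
        out = an.disambiguate_equal(
            self._equal_call(), [rec("c", 0, 30_000)], [rec("c", 50_000, 79_000)])
        assert out["c"].category == "equal" and not out["c"].disambiguated

    def test_missing_second_pass_warns_and_keeps(self):
        with pytest.warns(UserWarning, match="second-pass"):
            out = an.disambiguate_equal(self._equal_call(), [], [])
        assert out["c"].category == "equal"

    def test_never_increases_equal_count(self, dataset):
        calls = an.call_assembly(dataset.aln_a, dataset.aln_b, dataset.contigs)
        before = sum(1 for c in calls.values() if c.category == "equal")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = an.disambiguate_equal(calls, dataset.aln_a, dataset.aln_b)
        after = sum(1 for c in out.values() if c.category == "equal")
        assert after <= before


class TestTotals:
    def test_totals_partition_the_assembly(self):
        calls = [
            AncestryCall("a", 1_000_000, 0, 0, "A_dominant"),
            AncestryCall("b", 2_000_000, 0, 0, "B_dominant"),
            AncestryCall("c", 1_000_000, 0, 0, "equal"),
        ]
        totals = an.ancestry_bp_totals(calls)
        assert totals["A_dominant"]["bp"] == 1_000_000
        assert totals["B_dominant"]["bp"] == 2_000_000
        assert totals["equal"]["bp"] == 1_000_000
        assert sum(v["bp"] for v in totals.values()) == sum(c.length for c in calls)

    def test_empty_call_set(self):
        totals = an.ancestry_bp_totals([])
        assert all(v["n"] == 0 and v["bp"] == 0 for v in totals.values())

    def test_totals_match_truth_on_simulation(self, dataset):
        calls = an.call_assembly(dataset.aln_a, dataset.aln_b, dataset.contigs)
        totals = an.ancestry_bp_totals(calls)
        truth_bp = {"A": 0, "B": 0}
        for c in dataset.truth:
            if not c.is_chimeric:
                truth_bp[c.dominant_ancestry] += c.length
        # dominant categories should come within 5% of the planted pure bp
        assert totals["A_dominant"]["bp"] == pytest.approx(truth_bp["A"], rel=0.05)
        assert totals["B_dominant"]["bp"] == pytest.approx(truth_bp["B"], rel=0.05)
        assert sum(v["bp"] for v in totals.values()) == dataset.contigs.total_bp


class TestRecombRatio:
    def test_headline_comparison(self):
        # 6819 recombinant contigs over 56 chromosomes vs 407 over 10
        ratio = an.normalized_recomb_ratio(6819, 56, 407, 10)
        assert ratio == pytest.approx(2.99, abs=0.01)

    def test_equal_rates_give_unity(self):
        assert an.normalized_recomb_ratio(10, 5, 20, 10) == 1.0

    def test_scale_invariant_and_reciprocal(self):
        assert an.normalized_recomb_ratio(68190, 56, 4070, 10) == pytest.approx(
            an.normalized_recomb_ratio(6819, 56, 407, 10))
        assert an.normalized_recomb_ratio(407, 10, 6819, 56) == pytest.approx(
            1 / an.normalized_recomb_ratio(6819, 56, 407, 10))

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            an.normalized_recomb_ratio(1, 0, 1, 1)


class TestDepthPartition:
    def test_length_weighted_median_and_partition(self):
        depths = [DepthRecord("a", 13, 1_000_000), DepthRecord("b", 13, 1_000_000),
                  DepthRecord("c", 40, 2_000_000)]
        median, single, multi = an.depth_partition(depths, PARAMS)
        assert median == 13
        assert (single, multi) == (2_000_000, 2_000_000)

    def test_uniform_depth_has_no_multi_copy(self):
        depths = [DepthRecord(f"c{i}", 13, 10_000) for i in range(5)]
        _, single, multi = an.depth_partition(depths, PARAMS)
        assert multi == 0 and single == 50_000

    def test_tie_at_cutoff_is_single_copy(self):
        depths = [DepthRecord("a", 10, 1_000), DepthRecord("b", 15, 1_000)]
        # median 10 (lower weighted median), cutoff 15: depth == 15 stays single
        _, _, multi = an.depth_partition(depths, PARAMS)
        assert multi == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            an.depth_partition([], PARAMS)


class TestUnplacedConcordance:
    def _painting(self):
        return {"chr1": [(0, 60_000, "A_dominant"), (60_000, 100_000, "B_dominant")]}

    def test_concordance_counts_matching_painted_bp(self):
        calls = [AncestryCall("u1", 100_000, 90_000, 0, "A_dominant")]
        alns = [rec("u1", 0, 100_000, rid="chr1")]
        aligned, conc = an.unplaced_concordance(calls, alns, self._painting())
        assert aligned == pytest.approx(1.0)
        assert conc == pytest.approx(0.60)

    def test_no_alignments_reports_absent_concordance(self):
        calls = [AncestryCall("u1", 100_000, 0, 0, "unaligned")]
        aligned, conc = an.unplaced_concordance(calls, [], self._painting())
        assert aligned == 0.0 and conc is None

    def test_equal_contigs_excluded_from_concordance(self):
        calls = [AncestryCall("u1", 100_000, 45_000, 45_000, "equal")]
        alns = [rec("u1", 0, 100_000, rid="chr1")]
        aligned, conc = an.unplaced_concordance(calls, alns, self._painting())
        assert aligned == 1.0 and conc is None

    def test_truth_derived_concordance(self, dataset):
        from subpaint import report
        from subpaint.synthdata import export_unplaced_truth_alignments

        ds = dataset
        calls = an.call_assembly(ds.aln_a, ds.aln_b, ds.contigs)
        placed = {cid: c for cid, c in calls.items() if cid not in set(ds.unplaced_ids)}
        unplaced = {cid: calls[cid] for cid in ds.unplaced_ids}
        tracks = report.build_painting(ds.placements, placed, min_display_bp=0)
        amap = report.painting_ancestry_map(tracks)
        alns = export_unplaced_truth_alignments(ds.truth, ds.placements, ds.unplaced_ids)
        aligned, conc = an.unplaced_concordance(unplaced, alns, amap)

        # oracle: pairwise source-window overlaps between unplaced and placed
        # contigs (each placed contig occupies its own disjoint scaffold
        # range, so pairwise sums equal the merged-footprint accounting)
        placed_by_chrom = {}
        for p in ds.placements:
            if p.is_gap:
                continue
            t = ds.truth[p.component_id]
            placed_by_chrom.setdefault(t.chrom, []).append(t)
        num = denom = 0
        for uid in ds.unplaced_ids:
            u = ds.truth[uid]
            if calls[uid].category not in ("A_dominant", "B_dominant"):
                continue
            for t in placed_by_chrom.get(u.chrom, []):
                if calls[t.contig_id].category not in ("A_dominant", "B_dominant"):
                    continue
                lo = max(u.source_start, t.source_start)
                hi = min(u.source_start + u.length, t.source_start + t.length)
                if lo >= hi:
                    continue
                denom += hi - lo
                if calls[uid].category == calls[t.contig_id].category:
                    num += hi - lo
        assert denom > 0
        assert conc == pytest.approx(num / denom)
        assert 0 < aligned <= 1


class TestCompareGenomes:
    def test_genome_vs_identical_copy(self):
        lengths = ContigSet({"s1": 1_000, "s2": 2_000})
        recs = [rec(n, 0, L, rid=n, idy=100.0) for n, L in lengths.lengths.items()]
        out = an.compare_genomes(recs, lengths, lengths)
        assert out["query_covered_fraction"] == 1.0
        assert out["ref_covered_fraction"] == 1.0
        assert out["weighted_identity"] == 100.0

    def test_empty_record_set(self):
        lengths = ContigSet({"s1": 1_000})
        out = an.compare_genomes([], lengths, lengths)
        assert out["query_covered_fraction"] == 0.0
        assert out["weighted_identity"] is None
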