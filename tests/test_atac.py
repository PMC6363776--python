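"""Open-chromatin operations: merging, consensus, partition, annotation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lncrep.atac import (
    ConsensusPeakSet,
    annotate_features,
    consensus_across_replicates,
    merge_close_peaks,
    merge_intervals,
    partition_by_condition,
    peaks_at_lnc_tss,
    tss_profile,
)
from lncrep.model import (
    ConfigError,
    GeneModel,
    GenomicInterval,
    PeakCollection,
    PipelineConfig,
    TranscriptModel,
    ValidationError,
)

CFG = PipelineConfig()


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def coll(peaks, rep="r1", cond="X"):
    return PeakCollection(condition=cond, replicate=rep, peaks=list(peaks))


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 5000), st.integers(1, 300)).map(
        lambda t: iv(t[0], t[0] + t[1])
    ),
    min_size=1,
    max_size=25,
)


class TestMergeClosePeaks:
    def test_gap_below_threshold_merges(self):
        merged = merge_intervals([iv(0, 100), iv(150, 250)], 100)
        assert [(p.start, p.end) for p in merged] == [(0, 250)]

    def test_gap_exactly_threshold_does_not_merge(self):
        merged = merge_intervals([iv(0, 100), iv(200, 300)], 100)
        assert len(merged) == 2

    def test_transitive_chain_merges(self):
        merged = merge_intervals([iv(0, 10), iv(50, 60), iv(100, 110)], 100)
        assert [(p.start, p.end) for p in merged] == [(0, 110)]

    @given(intervals_strategy)
    def test_idempotent(self, peaks):
        once = merge_intervals(peaks, 100)
        twice = merge_intervals(once, 100)
        assert [(p.start, p.end) for p in once] == [(p.start, p.end) for p in twice]

    @given(intervals_strategy)
    def test_order_independent(self, peaks):
        fwd = merge_intervals(peaks, 100)
        rev = merge_intervals(list(reversed(peaks)), 100)
        assert [(p.start, p.end) for p in fwd] == [(p.start, p.end) for p in rev]

    def test_collection_wrapper_respects_config(self):
        c = coll([iv(0, 100), iv(150, 250)])
        merged = merge_close_peaks(c, CFG)
        assert len(merged.peaks) == 1


class TestConsensus:
    def test_jittered_replicates_give_union_peak(self):
        reps = [
            coll([iv(100, 200)], "r1"),
            coll([iv(110, 210)], "r2"),
            coll([iv(90, 195)], "r3"),
        ]
        result = consensus_across_replicates(reps, CFG)
        assert [(p.start, p.end) for p in result.peaks] == [(90, 210)]
        assert result.support == [("r1", "r2", "r3")]

    def test_peak_in_two_of_three_replicates_absent(self):
        reps = [
            coll([iv(100, 200)], "r1"),
            coll([iv(100, 200)], "r2"),
            coll([iv(5000, 5100)], "r3"),
        ]
        assert consensus_across_replicates(reps, CFG).peaks == []

    def test_single_replicate_identity(self):
        c = coll([iv(0, 100), iv(500, 600)])
        result = consensus_across_replicates([c], CFG)
        assert [(p.start, p.end) for p in result.peaks] == [(0, 100), (500, 600)]

    def test_zero_replicates_is_config_error(self):
        with pytest.raises(ConfigError):
            consensus_across_replicates([], CFG)

    def test_intersection_core_anti_monotone_in_replicates(self):
        # base-level consensus coverage can only shrink as replicates are
        # added; checked in intersection mode, where regions are the core
        # bases covered by every replicate
        rng = np.random.default_rng(3)
        for _ in range(30):
            reps = []
            for r in range(3):
                peaks = [
                    iv(int(s), int(s) + int(w))
                    for s, w in zip(
                        rng.integers(0, 4000, 8), rng.integers(20, 300, 8)
                    )
                ]
                reps.append(coll(peaks, f"r{r}"))

            def coverage(cons):
                return sum(p.length for p in cons.peaks)

            one = coverage(consensus_across_replicates(reps[:1], CFG, mode="intersection"))
            two = coverage(consensus_across_replicates(reps[:2], CFG, mode="intersection"))
            three = coverage(consensus_across_replicates(reps, CFG, mode="intersection"))
            assert three <= two <= one

    def test_intersection_mode_returns_core(self):
        reps = [coll([iv(100, 300)], "r1"), coll([iv(200, 400)], "r2")]
        cons = consensus_across_replicates(reps, CFG, mode="intersection")
        assert [(p.start, p.end) for p in cons.peaks] == [(200, 300)]


class TestPartition:
    def test_toy_overlap_matrix(self):
        # p1 overlaps all B replicates, p2 none, p3 exactly one of two
        cons_a = ConsensusPeakSet("A", [iv(0, 100), iv(1000, 1100), iv(2000, 2100)])
        cons_b = ConsensusPeakSet("B", [iv(0, 100)])
        reps_a = [coll([iv(0, 100), iv(1000, 1100), iv(2000, 2100)], f"a{i}", "A") for i in range(3)]
        reps_b = [
            coll([iv(0, 100), iv(2000, 2100)], "b1", "B"),
            coll([iv(0, 100)], "b2", "B"),
        ]
        part = partition_by_condition(cons_a, reps_a, cons_b, reps_b)
        assert len(part.common_a) == 1
        assert len(part.a_specific) == 1
        assert len(part.excluded_a_partial) == 1
        assert len(part.common_b) == 1

    def test_empty_other_condition_all_specific(self):
        cons_a = ConsensusPeakSet("A", [iv(0, 100), iv(500, 600)])
        cons_b = ConsensusPeakSet("B", [])
        part = partition_by_condition(
            cons_a, [coll([iv(0, 100)], "a1", "A")], cons_b, [coll([], "b1", "B")]
        )
        assert len(part.a_specific) == 2
        assert len(part.b_specific) == 0

    def test_identical_conditions_all_common(self):
        peaks = [iv(0, 100), iv(500, 600)]
        cons = lambda c: ConsensusPeakSet(c, list(peaks))
        reps = lambda c: [coll(peaks, f"{c}{i}", c) for i in range(2)]
        part = partition_by_condition(cons("A"), reps("A"), cons("B"), reps("B"))
        assert len(part.common_a) == 2 and len(part.common_b) == 2
        assert not part.a_specific and not part.b_specific

    def test_additivity_on_simulated_data(self, zero_noise_run):
        _, result = zero_noise_run
        counts = result.partition.counts()
        n_a = len(result.cells["A"].consensus)
        n_b = len(result.cells["B"].consensus)
        assert counts["a_specific"] + counts["common_a"] + counts["excluded_a_partial"] == n_a
        assert counts["b_specific"] + counts["common_b"] + counts["excluded_b_partial"] == n_b


def _ref_gene(tss_window_gene=True):
    # + strand gene at [10_000, 14_000): exons [10_000,10_500) and [13_500,14_000)
    t = TranscriptModel(
        transcript_id="g.t",
        gene_id="g",
        chrom="chr1",
        strand="+",
        exons=(
            GenomicInterval("chr1", 10_000, 10_500, "+"),
            GenomicInterval("chr1", 13_500, 14_000, "+"),
        ),
        biotype="protein_coding",
    )
    return GeneModel("g", "chr1", "+", "protein_coding", [t])


class TestFeatureAnnotation:
    @pytest.mark.parametrize(
        "peak,expected",
        [
            (iv(9_600, 9_800), "promoter"),  # midpoint 300 bp upstream of TSS
            (iv(10_150, 10_350), "exon"),
            (iv(11_900, 12_100), "intron"),
            (iv(50_000, 50_200), "intergenic"),
            (iv(14_100, 14_500), "tts_3utr_other"),  # just downstream of the TTS
        ],
    )
    def test_midpoint_precedence(self, peak, expected):
        cons = ConsensusPeakSet("A", [peak])
        ann = annotate_features(cons, [_ref_gene()], CFG)
        assert ann.features == [expected]

    def test_every_peak_gets_exactly_one_label(self, zero_noise_run):
        _, result = zero_noise_run
        ann = result.cells["A"].features
        assert len(ann.features) == len(result.cells["A"].consensus)
        counts = ann.counts()
        assert sum(counts.values()) == len(ann.features)


class TestPeaksAtLncTss:
    def test_planted_specific_peaks_found(self, zero_noise_run):
        dataset, result = zero_noise_run
        pairs = result.tss_pairs["A"]
        truth = dataset.truth.repertoires["A"]
        # exactly the repertoire entries specific to A carry an A-specific
        # peak on their TSS (shared entries sit on common peaks)
        expected = {
            tid for tid, e in truth.items() if e.role in ("a_only",)
        }
        assert set(pairs["transcript_id"]) == expected

    def test_adjacent_peak_does_not_pair(self, zero_noise_run):
        _, result = zero_noise_run
        rep = result.cells["A"].repertoire
        # peaks far from every TSS never produce pairs
        far = [iv(3_999_000, 3_999_100)]
        assert peaks_at_lnc_tss(far, rep).empty

    def test_empty_repertoire_empty_table(self, zero_noise_run):
        _, result = zero_noise_run
        rep = result.cells["A"].repertoire
        empty = type(rep)(cell_type="x", entries=[], config=rep.config)
        assert peaks_at_lnc_tss([iv(0, 100)], empty).empty


class TestTssProfile:
    def test_centred_peak_fills_central_bins(self):
        peaks = [iv(4_500, 5_500)]
        m = tss_profile(peaks, [("chr1", 5_000, "+")], window_bp=2_000, bin_bp=100)
        assert m.shape == (1, 20)
        assert np.allclose(m[0, 5:15], 1.0)
        assert np.allclose(m[0, :5], 0.0) and np.allclose(m[0, 15:], 0.0)

    def test_no_peaks_zero_matrix(self):
        m = tss_profile([], [("chr1", 5_000, "+")], 2_000, 100)
        assert not m.any()

    def test_minus_strand_orientation(self):
        # peak strictly downstream of a minus-strand TSS appears on the right
        peaks = [iv(3_000, 4_000)]  # genomically left of the TSS
        m = tss_profile(peaks, [("chr1", 5_000, "-")], 4_000, 100)
        assert m[0, : 20].sum() == 0
        assert m[0, 20:].sum() > 0

    def test_window_must_be_even_multiple(self):
        with pytest.raises(ValidationError):
            tss_profile([], [("chr1", 0, "+")], 2_000, 300)
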