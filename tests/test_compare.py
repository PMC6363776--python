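"""Isoform correspondence matching and specificity classification."""

import pytest

from lncrep.compare import (
    candidate_pair,
    classify_specificity,
    compare_protein_coding,
    compare_repertoires,
    harmonize_for_comparison,
    match_transcripts,
    shared_exonic_length,
)
from lncrep.model import (
    ExpressionTable,
    GenomicInterval,
    PipelineConfig,
    TranscriptModel,
)
from lncrep.simulate import make_correspondence_instance

import pandas as pd

CFG = PipelineConfig()


def transcript(exons, strand="+", tid="t1", gid=None, chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid or f"{tid}.g",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


THREE_EXONS = [(0, 1000), (2000, 3000), (4000, 5000)]


def shifted(exons, which, delta):
    out = []
    for i, (s, e) in enumerate(exons):
        if i == which:
            out.append((s + delta, e + delta))
        else:
            out.append((s, e))
    return out


class TestCandidatePair:
    def test_identical_chains_match_perfectly(self):
        a = transcript(THREE_EXONS, tid="a")
        b = transcript(THREE_EXONS, tid="b")
        pair = candidate_pair(a, b, CFG)
        assert pair is not None
        assert pair.reciprocal_overlap_a == pair.reciprocal_overlap_b == 1.0
        assert pair.exon_deltas == (0, 0, 0)

    @pytest.mark.parametrize("delta,matched", [(50, True), (51, False), (60, False)])
    def test_internal_exon_tolerance_boundary(self, delta, matched):
        a = transcript(THREE_EXONS, tid="a")
        b = transcript(shifted(THREE_EXONS, 1, delta), tid="b")
        assert (candidate_pair(a, b, CFG) is not None) is matched

    def test_outer_exon_tolerance_is_500(self):
        # first-exon start moved 400 bp with identical internal boundaries
        two = [(0, 5000), (6000, 11_000)]
        a = transcript(two, tid="a")
        b = transcript([(400, 5000), (6000, 11_000)], tid="b")
        pair = candidate_pair(a, b, CFG)
        assert pair is not None
        b_far = transcript([(501, 5000), (6000, 11_000)], tid="c")
        assert candidate_pair(a, b_far, CFG) is None

    def test_reciprocal_overlap_fails_on_either_side(self):
        a = transcript([(0, 1000)], tid="a")
        b = transcript([(0, 850)], tid="b")  # shared 850 = 85% of a
        assert candidate_pair(a, b, CFG) is None

    def test_exon_count_must_match(self):
        a = transcript(THREE_EXONS, tid="a")
        b = transcript(THREE_EXONS[:2], tid="b")
        assert candidate_pair(a, b, CFG) is None

    def test_strand_compatibility(self):
        a = transcript([(0, 1000)], tid="a", strand="+")
        assert candidate_pair(a, transcript([(0, 1000)], tid="b", strand="-"), CFG) is None
        assert candidate_pair(a, transcript([(0, 1000)], tid="b", strand="."), CFG) is not None

    def test_shared_exonic_length_is_spliced_not_span(self):
        a = transcript(THREE_EXONS, tid="a")
        b = transcript([(0, 1000), (1500, 3000), (4000, 5000)], tid="b")
        assert shared_exonic_length(a, b) == 3000  # introns contribute nothing


class TestMatchTranscripts:
    def test_symmetry(self):
        a, b, _ = make_correspondence_instance(20, seed=5, jitter="within")
        fwd = {
            (p.transcript_a.transcript_id, p.transcript_b.transcript_id)
            for p in match_transcripts(a, b, CFG)
        }
        rev = {
            (p.transcript_b.transcript_id, p.transcript_a.transcript_id)
            for p in match_transcripts(b, a, CFG)
        }
        assert fwd == rev

    def test_recovery_inside_and_outside_tolerances(self):
        a, b, expected = make_correspondence_instance(20, seed=5, jitter="within")
        found = {
            (p.transcript_a.transcript_id, p.transcript_b.transcript_id)
            for p in match_transcripts(a, b, CFG)
        }
        assert found == expected
        a2, b2, _ = make_correspondence_instance(20, seed=5, jitter="beyond")
        assert match_transcripts(a2, b2, CFG) == []

    def test_tolerance_monotonicity(self):
        a, b, _ = make_correspondence_instance(30, seed=9, jitter="within")
        tight = CFG.replace(internal_exon_tol_bp=10, outer_exon_tol_bp=100)
        loose = CFG.replace(internal_exon_tol_bp=100, outer_exon_tol_bp=1000)
        assert len(match_transcripts(a, b, tight)) <= len(match_transcripts(a, b, CFG))
        assert len(match_transcripts(a, b, CFG)) <= len(match_transcripts(a, b, loose))

    def test_ambiguous_partner_flagged_and_best_kept(self):
        a = [transcript(THREE_EXONS, tid="a")]
        perfect = transcript(THREE_EXONS, tid="b_good")
        close = transcript(shifted(THREE_EXONS, 1, 40), tid="b_close")
        pairs = match_transcripts(a, [perfect, close], CFG)
        assert len(pairs) == 1
        assert pairs[0].transcript_b.transcript_id == "b_good"
        assert pairs[0].ambiguous


class TestSpecificity:
    def test_empty_other_side_all_specific(self):
        a = [transcript(THREE_EXONS, tid="a")]
        calls_a, calls_b = classify_specificity(a, [], [])
        assert calls_a == {"a": "specific_gene"} and calls_b == {}

    def test_identical_sides_all_same_isoform(self):
        a = [transcript(THREE_EXONS, tid="a")]
        b = [transcript(THREE_EXONS, tid="b")]
        pairs = match_transcripts(a, b, CFG)
        calls_a, calls_b = classify_specificity(a, b, pairs)
        assert calls_a == {"a": "same_gene_same_isoform"}
        assert calls_b == {"b": "same_gene_same_isoform"}

    def test_planted_construction_counts(self):
        """10 shared isoforms, 5 shared genes with swapped isoforms,
        20 unique genes per side -> calls (10, 5, 20)."""
        a_side, b_side = [], []
        base = 0
        for i in range(10):  # identical isoforms
            exons = [(base, base + 1000), (base + 2000, base + 3000)]
            a_side.append(transcript(exons, tid=f"as{i}"))
            b_side.append(transcript(exons, tid=f"bs{i}"))
            base += 10_000
        for i in range(5):  # same locus, different exon count
            exons3 = [(base, base + 1000), (base + 2000, base + 3000), (base + 4000, base + 5000)]
            exons2 = [(base, base + 1000), (base + 4000, base + 5000)]
            a_side.append(transcript(exons3, tid=f"ag{i}"))
            b_side.append(transcript(exons2, tid=f"bg{i}"))
            base += 10_000
        for i in range(20):  # unique loci per side
            a_side.append(transcript([(base, base + 800)], tid=f"au{i}"))
            base += 10_000
            b_side.append(transcript([(base, base + 800)], tid=f"bu{i}"))
            base += 10_000
        pairs = match_transcripts(a_side, b_side, CFG)
        calls_a, calls_b = classify_specificity(a_side, b_side, pairs)
        for calls in (calls_a, calls_b):
            counts = pd.Series(calls).value_counts().to_dict()
            assert counts == {
                "same_gene_same_isoform": 10,
                "same_gene_specific_isoform": 5,
                "specific_gene": 20,
            }

    def test_level_counts_partition_comparable_size(self, zero_noise_run):
        _, result = zero_noise_run
        spec = result.specificity
        for side, calls in (("a", spec.calls_a), ("b", spec.calls_b)):
            counts = spec.counts(side)
            assert sum(counts.values()) == len(calls)

    def test_zero_noise_matches_planted_levels(self, zero_noise_run):
        dataset, result = zero_noise_run
        assert result.specificity.calls_a == dataset.truth.specificity["A"]
        assert result.specificity.calls_b == dataset.truth.specificity["B"]


class TestHarmonization:
    def test_both_sides_stranded_identity(self, zero_noise_run):
        dataset, result = zero_noise_run
        rep = result.cells["A"].repertoire
        coding = [g for g in dataset.reference if g.is_coding]
        comparable, excluded = harmonize_for_comparison(rep, coding, True, CFG)
        assert excluded == [] and len(comparable) == len(rep)

    def test_nonstranded_side_drops_novel_monoexonic_near_genes(self, paper_like):
        from lncrep.pipeline import run_cell

        rep = run_cell(paper_like, "A").repertoire
        coding = [g for g in paper_like.reference if g.is_coding]
        comparable, excluded = harmonize_for_comparison(rep, coding, False, CFG)
        assert {e.transcript_id for e in excluded} == paper_like.truth.comparison_excluded["A"]
        for e in excluded:  # only unannotated monoexonic entries qualify
            assert e.transcript.is_monoexonic and e.novelty == "novel"
        assert len(comparable) + len(excluded) == len(rep)

    def test_multiexonic_never_excluded(self, paper_like):
        from lncrep.pipeline import run_cell

        rep = run_cell(paper_like, "A").repertoire
        coding = [g for g in paper_like.reference if g.is_coding]
        _, excluded = harmonize_for_comparison(rep, coding, False, CFG)
        assert all(e.transcript.is_monoexonic for e in excluded)


class TestProteinCodingComparison:
    def _expr(self, transcripts):
        return ExpressionTable(
            pd.DataFrame(
                {f"r{i+1}": [5.0] * len(transcripts) for i in range(3)},
                index=[t.transcript_id for t in transcripts],
            )
        )

    def test_identical_sets_zero_specific(self):
        base = [transcript(THREE_EXONS, tid="a1"), transcript([(10_000, 11_000)], tid="a2")]
        other = [transcript(THREE_EXONS, tid="b1"), transcript([(10_000, 11_000)], tid="b2")]
        res = compare_protein_coding(base, other, self._expr(base), self._expr(other), CFG)
        assert res.frac_specific_transcripts_a == 0.0
        assert res.frac_specific_genes_b == 0.0

    def test_disjoint_sets_fully_specific(self):
        a = [transcript([(0, 1000)], tid="a1")]
        b = [transcript([(50_000, 51_000)], tid="b1")]
        res = compare_protein_coding(a, b, self._expr(a), self._expr(b), CFG)
        assert res.frac_specific_transcripts_a == 1.0
        assert res.frac_specific_genes_a == 1.0

    def test_planted_mixture_fractions(self, zero_noise_run):
        dataset, result = zero_noise_run
        assert result.coding.frac_specific_transcripts_a == pytest.approx(
            dataset.truth.coding_frac_specific["A"]
        )
        assert result.coding.frac_specific_transcripts_b == pytest.approx(
            dataset.truth.coding_frac_specific["B"]
        )

    def test_lnc_specific_fraction_higher_than_coding(self, paper_like):
        """The design the generator emulates: lncRNA repertoires are more
        cell-specific than protein-coding transcript sets."""
        from lncrep.pipeline import run_all

        result = run_all(paper_like)
        assert result.specificity.fraction_specific("a") > result.coding.frac_specific_transcripts_a
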