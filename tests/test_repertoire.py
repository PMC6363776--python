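"""Repertoire construction: every filter's semantics, order and provenance."""

import pandas as pd
import pytest

from lncrep.model import (
    ConfigError,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    TranscriptModel,
    ValidationError,
)
from lncrep.repertoire import (
    annotate_novelty,
    apply_monoexonic_rule,
    build_repertoire,
    filter_coding_potential,
    filter_expression,
    filter_length,
    filter_proximity,
    mark_tss_support,
    select_major_isoform,
)

CFG = PipelineConfig()


def transcript(exons, strand="+", tid="t1", gid=None, chrom="chr1", **kw):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid or f"{tid}.g",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        **kw,
    )


def coding_gene(span, strand="+", gid="cg1", chrom="chr1"):
    t = TranscriptModel(
        transcript_id=f"{gid}.t",
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exons=(GenomicInterval(chrom, *span, strand),),
        biotype="protein_coding",
    )
    return GeneModel(gid, chrom, strand, "protein_coding", [t])


def expr_table(rows, reps=3):
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"r{i+1}" for i in range(reps)]
    )
    return ExpressionTable(df.astype(float))


class TestLengthFilter:
    @pytest.mark.parametrize(
        "exons,kept",
        [
            ([(0, 199)], False),  # 199 bp: below the inclusive minimum
            ([(0, 200)], True),  # exactly 200 bp is kept (criterion is >=)
            ([(0, 150), (10_150, 10_300)], True),  # spliced 300 despite 10 kb intron
        ],
    )
    def test_boundary(self, exons, kept):
        survivors = filter_length([transcript(exons)], CFG)
        assert bool(survivors) is kept


class TestExpressionFilter:
    @pytest.mark.parametrize(
        "values,kept",
        [
            ((1.2, 0.0, 0.5), True),  # one >= 1 FPKM, two non-null
            ((1.5, 0.0, 0.0), False),  # only one non-null value
            ((0.9, 0.8, 0.99), False),  # no replicate reaches 1 FPKM
            ((1.0, 0.5, 0.0), True),  # exactly 1 FPKM counts as detected
        ],
    )
    def test_boundary(self, values, kept):
        t = transcript([(0, 500)])
        table = expr_table({"t1": list(values)})
        assert bool(filter_expression([t], table, CFG)) is kept

    def test_missing_row_treated_as_zero(self):
        t = transcript([(0, 500)])
        table = expr_table({"other": [5.0, 5.0, 5.0]})
        assert filter_expression([t], table, CFG) == []

    def test_too_few_replicates_is_config_error(self):
        t = transcript([(0, 500)])
        table = expr_table({"t1": [2.0]}, reps=1)
        with pytest.raises(ConfigError):
            filter_expression([t], table, CFG)


class TestCodingPotentialFilter:
    @pytest.mark.parametrize(
        "score,kept", [(0.43, True), (0.44, False), (1.0, False), (0.0, True)]
    )
    def test_cutoff_is_exclusive(self, score, kept):
        t = transcript([(0, 500)])
        assert bool(filter_coding_potential([t], {"t1": score}, CFG)) is kept

    def test_missing_score_drops_with_warning(self, caplog):
        t = transcript([(0, 500)])
        with caplog.at_level("WARNING", logger="lncrep"):
            assert filter_coding_potential([t], {}, CFG) == []
        assert any("without coding score" in r.message for r in caplog.records)

    def test_out_of_range_score_rejected(self):
        t = transcript([(0, 500)])
        with pytest.raises(ValidationError):
            filter_coding_potential([t], {"t1": 1.2}, CFG)


class TestProximityFilter:
    def test_same_strand_within_1kb_dropped(self):
        lnc = transcript([(0, 500)], strand="+")
        gene = coding_gene((1000, 3000), strand="+")  # gap 500
        assert filter_proximity([lnc], [gene], CFG) == []

    def test_opposite_strand_within_1kb_kept(self):
        lnc = transcript([(0, 500)], strand="+")
        gene = coding_gene((1000, 3000), strand="-")
        assert len(filter_proximity([lnc], [gene], CFG)) == 1

    @pytest.mark.parametrize("gene_start,kept", [(1300, False), (1700, True)])
    def test_unknown_strand_tested_on_both_strands(self, gene_start, kept):
        # gaps of 800 (dropped) and 1200 (kept) from a monoexonic transcript
        lnc = transcript([(0, 500)], strand=".")
        gene = coding_gene((gene_start, gene_start + 2000), strand="-")
        assert bool(filter_proximity([lnc], [gene], CFG)) is kept

    def test_same_strand_overlap_dropped_opposite_kept(self):
        lnc = transcript([(1000, 1600)], strand="+")
        same = coding_gene((500, 2500), strand="+")
        anti = coding_gene((500, 2500), strand="-")
        assert filter_proximity([lnc], [same], CFG) == []
        assert len(filter_proximity([lnc], [anti], CFG)) == 1

    def test_exactly_1kb_gap_kept(self):
        # the rule is strict: "lower than 1 kb"
        lnc = transcript([(0, 500)], strand="+")
        gene = coding_gene((1500, 3000), strand="+")  # gap exactly 1000
        assert len(filter_proximity([lnc], [gene], CFG)) == 1


class TestTssSupportAndMonoexonicRule:
    peak = [GenomicInterval("chr1", 100, 200)]

    @pytest.mark.parametrize(
        "tss_exon,expected",
        [((150, 700), True), ((200, 700), False), ((99, 700), False)],
    )
    def test_single_base_containment(self, tss_exon, expected):
        t = transcript([tss_exon], strand="+")
        assert mark_tss_support([t], self.peak)["t1"] is expected

    def test_minus_strand_uses_five_prime_end(self):
        t = transcript([(50, 151)], strand="-")  # TSS base = 150
        assert mark_tss_support([t], self.peak)["t1"] is True

    def test_unknown_strand_tests_both_span_ends(self):
        # TSS may be either end of a non-stranded monoexonic transcript
        left = transcript([(150, 700)], strand=".")
        right = transcript([(20, 151)], strand=".")
        neither = transcript([(300, 700)], strand=".")
        flags = mark_tss_support([left, right], self.peak)
        assert flags["t1"] is True
        flags = mark_tss_support([neither], self.peak)
        assert flags["t1"] is False

    @pytest.mark.parametrize(
        "n_exons,has_peak,kept",
        [(1, False, False), (1, True, True), (4, False, True), (4, True, True)],
    )
    def test_monoexonic_rule(self, n_exons, has_peak, kept):
        exons = [(i * 1000, i * 1000 + 200) for i in range(n_exons)]
        t = transcript(exons)
        out = apply_monoexonic_rule([t], {"t1": has_peak})
        assert bool(out) is kept


class TestMajorIsoform:
    def test_most_expressed_wins(self):
        a = transcript([(0, 800)], tid="iso1", gid="g")
        b = transcript([(0, 500)], tid="iso2", gid="g")
        table = expr_table({"iso1": [5.0] * 3, "iso2": [2.0] * 3})
        assert [t.transcript_id for t in select_major_isoform([a, b], table)] == ["iso1"]

    def test_tie_broken_by_length_then_id(self):
        long = transcript([(0, 800)], tid="zzz", gid="g")
        short = transcript([(0, 500)], tid="aaa", gid="g")
        table = expr_table({"zzz": [3.0] * 3, "aaa": [3.0] * 3})
        assert [t.transcript_id for t in select_major_isoform([long, short], table)] == ["zzz"]
        same_len = transcript([(0, 800)], tid="aaa", gid="g")
        table2 = expr_table({"zzz": [3.0] * 3, "aaa": [3.0] * 3})
        kept = select_major_isoform([long, same_len], table2)
        assert [t.transcript_id for t in kept] == ["aaa"]

    def test_single_isoform_identity(self):
        a = transcript([(0, 800)], tid="only", gid="g")
        assert select_major_isoform([a], expr_table({"only": [1.0] * 3})) == [a]


class TestNovelty:
    def test_class_codes(self):
        annotated = transcript([(0, 500)], tid="a", class_code="=", biotype="antisense")
        novel_dash = transcript([(0, 500)], tid="b", class_code="-")
        novel_x = transcript([(0, 500)], tid="c", class_code="x")
        not_lnc = transcript([(0, 500)], tid="d", class_code="=", biotype="protein_coding")
        kept, dropped = annotate_novelty([annotated, novel_dash, novel_x, not_lnc])
        assert {t.transcript_id: t.novelty for t in kept} == {
            "a": "annotated",
            "b": "novel",
            "c": "novel",
        }
        assert dropped == 1

    def test_fallback_intron_chain_match(self):
        ref_t = transcript([(0, 200), (500, 800)], tid="ref", biotype="lncRNA")
        ref = [GeneModel("rg", "chr1", "+", "lncRNA", [ref_t])]
        same_chain = transcript([(0, 200), (500, 900)], tid="q1")
        other_chain = transcript([(0, 200), (600, 900)], tid="q2")
        kept, dropped = annotate_novelty([same_chain, other_chain], ref)
        assert dropped == 0
        assert {t.transcript_id: t.novelty for t in kept} == {
            "q1": "annotated",
            "q2": "novel",
        }

    def test_fallback_monoexonic_reciprocal_span(self):
        ref_t = transcript([(0, 1000)], tid="ref", biotype="lncRNA")
        ref = [GeneModel("rg", "chr1", "+", "lncRNA", [ref_t])]
        good = transcript([(100, 900)], tid="q1")  # 80% reciprocal
        poor = transcript([(800, 3000)], tid="q2")  # 200/2200 on its own side
        kept, _ = annotate_novelty([good, poor], ref)
        assert {t.transcript_id: t.novelty for t in kept} == {
            "q1": "annotated",
            "q2": "novel",
        }

    def test_no_codes_and_no_reference_is_config_error(self):
        with pytest.raises(ConfigError):
            annotate_novelty([transcript([(0, 500)])], None)


class TestBuildRepertoire:
    def test_zero_noise_recovery_and_decoy_rejection(self, zero_noise_run):
        dataset, result = zero_noise_run
        for cell in ("A", "B"):
            rep = result.cells[cell].repertoire
            truth = dataset.truth.repertoires[cell]
            assert rep.transcript_ids == set(truth)
            for tid in dataset.truth.decoys[cell]:
                assert tid not in rep.transcript_ids

    def test_stage_counts_conserve(self, zero_noise_run):
        _, result = zero_noise_run
        for cell_result in result.cells.values():
            rep = cell_result.repertoire
            assert rep.n_input == len(rep) + sum(rep.drop_counts.values())

    def test_empty_input_empty_repertoire(self):
        rep = build_repertoire(
            transcripts=[],
            expr=expr_table({"x": [1.0] * 3}),
            scores={},
            consensus_peaks=[],
            reference=[],
            config=CFG,
        )
        assert len(rep) == 0

    def test_all_short_dropped_at_length_stage(self):
        ts = [transcript([(i * 1000, i * 1000 + 150)], tid=f"t{i}") for i in range(4)]
        rep = build_repertoire(
            transcripts=ts,
            expr=expr_table({f"t{i}": [2.0] * 3 for i in range(4)}),
            scores={f"t{i}": 0.1 for i in range(4)},
            consensus_peaks=[],
            reference=[],
            config=CFG,
        )
        assert len(rep) == 0
        assert rep.drop_counts["length"] == 4

    def test_determinism(self, tiny):
        from lncrep.pipeline import run_cell

        frames = [run_cell(tiny, "A").repertoire.to_frame() for _ in range(2)]
        pd.testing.assert_frame_equal(frames[0], frames[1])

    @pytest.mark.parametrize(
        "knob,grid",
        [
            ("min_fpkm", [0.5, 1.0, 2.0, 4.0, 8.0]),
            ("min_spliced_length", [100, 200, 400, 800, 1600]),
            ("min_nonzero_replicates", [0, 1, 2, 3]),
        ],
    )
    def test_monotone_in_thresholds(self, tiny, knob, grid):
        from lncrep.pipeline import run_cell

        sizes = [
            len(run_cell(tiny, "A", tiny.config.replace(**{knob: v})).repertoire)
            for v in grid
        ]
        assert sizes == sorted(sizes, reverse=True)
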