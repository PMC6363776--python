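"""Cross-repertoire isoform correspondence and specificity classification.

Two repertoires are compared by matching transcripts: a pair is accepted
when the shared exonic length is at least 90% of *each* transcript's
spliced length (reciprocal), the exon counts are equal, and each pair of
exons (matched by rank) differs by no more than 50 bp for internal exons
and 500 bp for the outermost exons. Every compared transcript then gets
exactly one specificity level: ``same_gene_same_isoform`` when matched,
``same_gene_specific_isoform`` when its gene corresponds to a gene in the
other repertoire without an isoform match, and ``specific_gene`` otherwise.

When one repertoire comes from a non-stranded library, the stranded side
first drops its unannotated monoexonic transcripts lying within 1 kb of a
protein-coding gene on any strand, so both sides are built from transcripts
with the same characteristics (harmonization); those entries stay in the
repertoire, they are only excluded from the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .classify import GeneIndex
from .model import (
    GeneModel,
    ExpressionTable,
    NOVELTY_NOVEL,
    PipelineConfig,
    TranscriptModel,
    strands_compatible,
)
from .repertoire import Repertoire, RepertoireEntry, filter_expression

logger = logging.getLogger("lncrep")

LEVELS = ("specific_gene", "same_gene_specific_isoform", "same_gene_same_isoform")


@dataclass
class CorrespondencePair:
    transcript_a: TranscriptModel
    transcript_b: TranscriptModel
    reciprocal_overlap_a: float
    reciprocal_overlap_b: float
    exon_deltas: tuple[int, ...]
    ambiguous: bool = False

    @property
    def score(self) -> float:
        return self.reciprocal_overlap_a + self.reciprocal_overlap_b


def shared_exonic_length(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total bp shared between two transcripts' exon sets (spliced overlap)."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    i = j = 0
    while i < len(a.exons) and j < len(b.exons):
        ea, eb = a.exons[i], b.exons[j]
        total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
        if ea.end <= eb.end:
            i += 1
        else:
            j += 1
    return total


def _exon_deltas_ok(
    a: TranscriptModel, b: TranscriptModel, config: PipelineConfig
) -> Optional[tuple[int, ...]]:
    """Per-rank exon coordinate offsets, or None when a tolerance is exceeded.

    First and last exons carry the outer tolerance on both boundaries
    (ragged transcript ends); internal exons carry the tight tolerance
    (splice sites are precise).
    """
    n = a.n_exons
    deltas = []
    for rank, (ea, eb) in enumerate(zip(a.exons, b.exons)):
        tol = (
            config.outer_exon_tol_bp
            if rank in (0, n - 1)
            else config.internal_exon_tol_bp
        )
        d_start = abs(ea.start - eb.start)
        d_end = abs(ea.end - eb.end)
        if d_start > tol or d_end > tol:
            return None
        deltas.append(max(d_start, d_end))
    return tuple(deltas)


def candidate_pair(
    a: TranscriptModel, b: TranscriptModel, config: PipelineConfig
) -> Optional[CorrespondencePair]:
    """Test one transcript pair against the correspondence criteria."""
    if a.chrom != b.chrom or not strands_compatible(a.strand, b.strand):
        return None
    if a.n_exons != b.n_exons:
        return None
    if not a.span.overlaps(b.span):
        return None
    shared = shared_exonic_length(a, b)
    frac_a = shared / a.spliced_length
    frac_b = shared / b.spliced_length
    if frac_a < config.reciprocal_overlap_frac or frac_b < config.reciprocal_overlap_frac:
        return None
    deltas = _exon_deltas_ok(a, b, config)
    if deltas is None:
        return None
    return CorrespondencePair(
        transcript_a=a,
        transcript_b=b,
        reciprocal_overlap_a=frac_a,
        reciprocal_overlap_b=frac_b,
        exon_deltas=deltas,
    )


def harmonize_for_comparison(
    repertoire: Repertoire,
    coding_genes: Iterable[GeneModel],
    other_side_stranded: bool,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[RepertoireEntry], list[RepertoireEntry]]:
    """Return (comparable entries, excluded entries).

    When either side of the comparison is non-stranded, unannotated
    monoexonic transcripts within ``proximity_bp`` of a protein-coding gene
    on *any* strand are excluded, because the non-stranded side could never
    have kept such transcripts. With both sides stranded this is the
    identity.
    """
    if other_side_stranded and repertoire.config.stranded_library:
        return list(repertoire.entries), []
    index = GeneIndex(g for g in coding_genes if g.is_coding)
    comparable, excluded = [], []
    for entry in repertoire.entries:
        t = entry.transcript
        if t.is_monoexonic and entry.novelty == NOVELTY_NOVEL:
            near = any(
                t.span.gap(g.span) < config.proximity_bp
                for g in index.genes_on(t.chrom)
            )
            if near:
                excluded.append(entry)
                continue
        comparable.append(entry)
    if excluded:
        logger.info(
            "harmonize(%s): %d monoexonic entries excluded from comparison",
            repertoire.cell_type,
            len(excluded),
        )
    return comparable, excluded


def match_transcripts(
    transcripts_a: Sequence[TranscriptModel],
    transcripts_b: Sequence[TranscriptModel],
    config: PipelineConfig = PipelineConfig(),
) -> list[CorrespondencePair]:
    """All accepted correspondence pairs between two transcript sets.

    Each transcript keeps at most one partner: accepted candidates are
    ranked by summed reciprocal overlap (ties broken by transcript ids) and
    taken greedily, so the result is symmetric in A and B. A transcript
    that had more than one accepted candidate is flagged ``ambiguous`` —
    the deterministic stand-in for manual curation, surfaced for review
    rather than silently resolved.
    """
    by_chrom_b: dict[str, list[TranscriptModel]] = {}
    for t in transcripts_b:
        by_chrom_b.setdefault(t.chrom, []).append(t)
    candidates: list[CorrespondencePair] = []
    for a in transcripts_a:
        for b in by_chrom_b.get(a.chrom, ()):
            pair = candidate_pair(a, b, config)
            if pair is not None:
                candidates.append(pair)

    n_cands_a: dict[str, int] = {}
    n_cands_b: dict[str, int] = {}
    for p in candidates:
        n_cands_a[p.transcript_a.transcript_id] = (
            n_cands_a.get(p.transcript_a.transcript_id, 0) + 1
        )
        n_cands_b[p.transcript_b.transcript_id] = (
            n_cands_b.get(p.transcript_b.transcript_id, 0) + 1
        )

    candidates.sort(
        key=lambda p: (
            -p.score,
            p.transcript_a.transcript_id,
            p.transcript_b.transcript_id,
        )
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    accepted: list[CorrespondencePair] = []
    for p in candidates:
        ta, tb = p.transcript_a.transcript_id, p.transcript_b.transcript_id
        if ta in used_a or tb in used_b:
            continue
        used_a.add(ta)
        used_b.add(tb)
        p.ambiguous = n_cands_a[ta] > 1 or n_cands_b[tb] > 1
        accepted.append(p)
    return accepted


@dataclass
class SpecificityResult:
    calls_a: dict[str, str]
    calls_b: dict[str, str]
    pairs: list[CorrespondencePair]
    excluded_a: list[str] = field(default_factory=list)
    excluded_b: list[str] = field(default_factory=list)

    def counts(self, side: str) -> dict[str, int]:
        calls = self.calls_a if side == "a" else self.calls_b
        out = {level: 0 for level in LEVELS}
        for level in calls.values():
            out[level] += 1
        return out

    def fraction_specific(self, side: str) -> float:
        """Fraction of compared transcripts that are cell-type specific
        (specific gene or specific isoform of a shared gene)."""
        calls = self.calls_a if side == "a" else self.calls_b
        if not calls:
            return 0.0
        n_specific = sum(
            1 for v in calls.values() if v != "same_gene_same_isoform"
        )
        return n_specific / len(calls)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"side": "a", "transcript_id": tid, "level": level}
            for tid, level in sorted(self.calls_a.items())
        ] + [
            {"side": "b", "transcript_id": tid, "level": level}
            for tid, level in sorted(self.calls_b.items())
        ]
        return pd.DataFrame(rows, columns=["side", "transcript_id", "level"])


def _gene_spans(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        genes.setdefault(t.gene_id, []).append(t)
    return genes


def classify_specificity(
    transcripts_a: Sequence[TranscriptModel],
    transcripts_b: Sequence[TranscriptModel],
    pairs: Sequence[CorrespondencePair],
) -> tuple[dict[str, str], dict[str, str]]:
    """Per-transcript specificity levels for both sides.

    Gene-level correspondence: two genes correspond iff any transcript pair
    between them matched, or their loci overlap by >= 1 bp on compatible
    strands. A matched transcript is ``same_gene_same_isoform``; an
    unmatched transcript of a corresponding gene is
    ``same_gene_specific_isoform``; the rest are ``specific_gene``.
    """
    matched_a = {p.transcript_a.transcript_id for p in pairs}
    matched_b = {p.transcript_b.transcript_id for p in pairs}
    genes_matched_a = {p.transcript_a.gene_id for p in pairs}
    genes_matched_b = {p.transcript_b.gene_id for p in pairs}

    def locus_overlaps(t: TranscriptModel, others: Sequence[TranscriptModel]) -> bool:
        span = t.span
        return any(
            strands_compatible(t.strand, o.strand) and span.overlaps(o.span)
            for o in others
        )

    def side(
        own: Sequence[TranscriptModel],
        other: Sequence[TranscriptModel],
        matched: set[str],
        genes_matched: set[str],
    ) -> dict[str, str]:
        calls = {}
        for t in own:
            if t.transcript_id in matched:
                calls[t.transcript_id] = "same_gene_same_isoform"
            elif t.gene_id in genes_matched or locus_overlaps(t, other):
                calls[t.transcript_id] = "same_gene_specific_isoform"
            else:
                calls[t.transcript_id] = "specific_gene"
        return calls

    return (
        side(transcripts_a, transcripts_b, matched_a, genes_matched_a),
        side(transcripts_b, transcripts_a, matched_b, genes_matched_b),
    )


def compare_repertoires(
    repertoire_a: Repertoire,
    repertoire_b: Repertoire,
    coding_genes: Sequence[GeneModel],
    config: PipelineConfig = PipelineConfig(),
) -> SpecificityResult:
    """Full comparison: harmonize, match and classify two lncRNA repertoires."""
    both_stranded = (
        repertoire_a.config.stranded_library and repertoire_b.config.stranded_library
    )
    comp_a, excl_a = harmonize_for_comparison(
        repertoire_a, coding_genes, repertoire_b.config.stranded_library, config
    )
    comp_b, excl_b = harmonize_for_comparison(
        repertoire_b, coding_genes, repertoire_a.config.stranded_library, config
    )
    ts_a = [e.transcript for e in comp_a]
    ts_b = [e.transcript for e in comp_b]
    pairs = match_transcripts(ts_a, ts_b, config)
    calls_a, calls_b = classify_specificity(ts_a, ts_b, pairs)
    result = SpecificityResult(
        calls_a=calls_a,
        calls_b=calls_b,
        pairs=pairs,
        excluded_a=[e.transcript_id for e in excl_a],
        excluded_b=[e.transcript_id for e in excl_b],
    )
    logger.info(
        "compare(%s vs %s): %d pairs; a=%s b=%s%s",
        repertoire_a.cell_type,
        repertoire_b.cell_type,
        len(pairs),
        result.counts("a"),
        result.counts("b"),
        "" if both_stranded else " (harmonized for non-stranded side)",
    )
    return result


@dataclass
class CodingComparison:
    calls_a: dict[str, str]
    calls_b: dict[str, str]
    pairs: list[CorrespondencePair]
    frac_specific_transcripts_a: float
    frac_specific_transcripts_b: float
    frac_specific_genes_a: float
    frac_specific_genes_b: float


def compare_protein_coding(
    transcripts_a: Sequence[TranscriptModel],
    transcripts_b: Sequence[TranscriptModel],
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    config: PipelineConfig = PipelineConfig(),
) -> CodingComparison:
    """Specificity of protein-coding transcript sets between two cell types.

    Coding transcripts pass only the expression filter (the lncRNA-specific
    filters do not apply), then go through the same matching and
    specificity machinery; transcript- and gene-level specific fractions
    are reported per side.
    """
    ts_a = filter_expression(transcripts_a, expr_a, config)
    ts_b = filter_expression(transcripts_b, expr_b, config)
    pairs = match_transcripts(ts_a, ts_b, config)
    calls_a, calls_b = classify_specificity(ts_a, ts_b, pairs)

    def gene_fraction(
        own: Sequence[TranscriptModel], calls: dict[str, str]
    ) -> float:
        genes = _gene_spans(own)
        if not genes:
            return 0.0
        n_specific = sum(
            1
            for gid, ts in genes.items()
            if all(calls[t.transcript_id] == "specific_gene" for t in ts)
        )
        return n_specific / len(genes)

    def transcript_fraction(calls: dict[str, str]) -> float:
        if not calls:
            return 0.0
        return sum(1 for v in calls.values() if v != "same_gene_same_isoform") / len(
            calls
        )

    return CodingComparison(
        calls_a=calls_a,
        calls_b=calls_b,
        pairs=pairs,
        frac_specific_transcripts_a=transcript_fraction(calls_a),
        frac_specific_transcripts_b=transcript_fraction(calls_b),
        frac_specific_genes_a=gene_fraction(ts_a, calls_a),
        frac_specific_genes_b=gene_fraction(ts_b, calls_b),
    )
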