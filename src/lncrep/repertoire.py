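"""Build a cell type's lncRNA repertoire from assembled transcripts.

The decision procedure keeps transcripts that are (i) >= 200 bp spliced
length, (ii) expressed at >= 1 FPKM in at least one replicate with at least
two non-null replicate values, and (iii) of low protein-coding potential
(CPAT-style score below 0.44); removes transcripts lying closer than 1 kb to
a protein-coding gene on the same strand (or of undetermined strand);
discards monoexonic transcripts without an open-chromatin peak at their TSS
(multiexonic transcripts are retained regardless, since polyadenylated
sequencing under-represents 5' exons); collapses each locus to its most
expressed isoform; and finally labels novelty and positional category.

Filters run in a fixed order and every stage's drop count is recorded in
the repertoire provenance so the arithmetic ``input = output + sum(drops)``
is auditable.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .classify import (
    ClassificationRules,
    ClosestGenes,
    GeneIndex,
    classify,
    find_closest_genes,
)
from .model import (
    ConfigError,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    LNC_BIOTYPES,
    NOVEL_CLASS_CODES,
    NOVELTY_ANNOTATED,
    NOVELTY_NOVEL,
    PipelineConfig,
    STRAND_UNKNOWN,
    TranscriptModel,
    ValidationError,
    group_by_gene,
    strands_compatible,
)

logger = logging.getLogger("lncrep")

#: order in which filters are applied (provenance keys)
STAGES = (
    "length",
    "expression",
    "coding_potential",
    "proximity",
    "monoexonic_no_tss_peak",
    "minor_isoform",
    "novelty",
)


@dataclass
class RepertoireEntry:
    transcript: TranscriptModel
    mean_fpkm: float
    novelty: str
    tss_has_peak: bool
    category: Optional[str] = None
    links: ClosestGenes = field(default_factory=ClosestGenes)

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id

    @property
    def gene_id(self) -> str:
        return self.transcript.gene_id


@dataclass
class Repertoire:
    """Accepted transcript set of one cell type, one major isoform per locus."""

    cell_type: str
    entries: list[RepertoireEntry]
    config: PipelineConfig
    drop_counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def transcript_ids(self) -> set[str]:
        return {e.transcript_id for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.entries, key=lambda e: e.transcript_id):
            t = e.transcript
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "gene_id": t.gene_id,
                    "locus": t.span.locus,
                    "strand": t.strand,
                    "category": e.category,
                    "novelty": e.novelty,
                    "exon_count": t.n_exons,
                    "spliced_length": t.spliced_length,
                    "mean_fpkm": round(e.mean_fpkm, 4),
                    "tss_has_peak": e.tss_has_peak,
                    "overlapped_gene": e.links.overlapped.gene_id
                    if e.links.overlapped
                    else None,
                    "upstream_gene": e.links.upstream.gene_id if e.links.upstream else None,
                    "upstream_distance": e.links.upstream.distance
                    if e.links.upstream
                    else None,
                    "downstream_gene": e.links.downstream.gene_id
                    if e.links.downstream
                    else None,
                    "downstream_distance": e.links.downstream.distance
                    if e.links.downstream
                    else None,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def filter_length(
    transcripts: Sequence[TranscriptModel], config: PipelineConfig
) -> list[TranscriptModel]:
    """Keep transcripts whose spliced length is >= the minimum (inclusive)."""
    return [t for t in transcripts if t.spliced_length >= config.min_spliced_length]


def filter_expression(
    transcripts: Sequence[TranscriptModel],
    expr: ExpressionTable,
    config: PipelineConfig,
) -> list[TranscriptModel]:
    """Keep transcripts detected at >= min_fpkm in enough replicates and with
    enough non-null replicate values.

    A transcript missing from the table counts as all-zero (logged).
    """
    if expr.n_replicates < config.min_nonzero_replicates:
        raise ConfigError(
            f"expression table has {expr.n_replicates} replicates but "
            f"min_nonzero_replicates={config.min_nonzero_replicates}"
        )
    kept = []
    missing = 0
    for t in transcripts:
        if t.transcript_id not in expr.data.index:
            missing += 1
        values = expr.values(t.transcript_id)
        n_detected = int((values >= config.min_fpkm).sum())
        n_nonzero = int((values > 0).sum())
        if (
            n_detected >= config.min_detected_replicates
            and n_nonzero >= config.min_nonzero_replicates
        ):
            kept.append(t)
    if missing:
        logger.warning("%d transcripts missing from expression table (treated as 0)", missing)
    return kept


def filter_coding_potential(
    transcripts: Sequence[TranscriptModel],
    scores: dict[str, float],
    config: PipelineConfig,
) -> list[TranscriptModel]:
    """Keep transcripts with coding-potential score strictly below the cutoff.

    Scores at or above the cutoff are treated as coding (the published
    cutoff semantics); a missing score drops the transcript with a warning.
    """
    kept = []
    missing = 0
    for t in transcripts:
        score = scores.get(t.transcript_id)
        if score is None:
            missing += 1
            continue
        if not (0.0 <= score <= 1.0):
            raise ValidationError(
                f"{t.transcript_id}: coding score {score} outside [0, 1]"
            )
        if score < config.coding_cutoff:
            kept.append(t)
    if missing:
        logger.warning("%d transcripts without coding score dropped", missing)
    return kept


def filter_proximity(
    transcripts: Sequence[TranscriptModel],
    coding_genes: Iterable[GeneModel],
    config: PipelineConfig,
) -> list[TranscriptModel]:
    """Eliminate transcripts lying < proximity_bp from a same-strand coding gene.

    Distance is the gap between spans (0 when overlapping). Strand-unknown
    transcripts are tested against genes on both strands — the non-stranded
    library case. Opposite-strand overlaps are retained so that
    overlapping-antisense lncRNAs can exist at all.
    """
    index = GeneIndex(g for g in coding_genes if g.is_coding)
    kept = []
    for t in transcripts:
        span = t.span
        too_close = False
        for gene in index.genes_on(t.chrom):
            if not strands_compatible(t.strand, gene.strand):
                continue
            if span.gap(gene.span) < config.proximity_bp:
                too_close = True
                break
        if not too_close:
            kept.append(t)
    return kept


class _PeakIndex:
    """Sorted per-chromosome peak intervals for single-base containment."""

    def __init__(self, peaks: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda p: p.start)
            self._starts[chrom] = [p.start for p in lst]
            self._ends[chrom] = [p.end for p in lst]

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]


def mark_tss_support(
    transcripts: Sequence[TranscriptModel],
    consensus_peaks: Iterable[GenomicInterval],
) -> dict[str, bool]:
    """Flag transcripts whose TSS base falls inside a consensus peak.

    The intersection is between a peak interval and the single first
    transcribed nucleotide. For strand-unknown transcripts either span
    endpoint may be the true TSS, so a peak containing either endpoint
    counts (logged); consensus peaks are non-overlapping, merged intervals.
    """
    index = _PeakIndex(consensus_peaks)
    flags: dict[str, bool] = {}
    n_unknown = 0
    for t in transcripts:
        if t.strand == STRAND_UNKNOWN:
            n_unknown += 1
        flags[t.transcript_id] = any(
            index.contains(t.chrom, pos) for pos in t.candidate_tss_positions()
        )
    if n_unknown:
        logger.info(
            "%d strand-unknown transcripts: TSS support tested at both span ends",
            n_unknown,
        )
    return flags


def apply_monoexonic_rule(
    transcripts: Sequence[TranscriptModel], tss_flags: dict[str, bool]
) -> list[TranscriptModel]:
    """Drop monoexonic transcripts lacking TSS peak support; keep all
    multiexonic transcripts regardless (their splice junctions already
    distinguish them from transcriptional background)."""
    return [
        t
        for t in transcripts
        if not t.is_monoexonic or tss_flags.get(t.transcript_id, False)
    ]


def select_major_isoform(
    transcripts: Sequence[TranscriptModel], expr: ExpressionTable
) -> list[TranscriptModel]:
    """Keep one transcript per gene locus: the most expressed isoform.

    "Most expressed" is the mean FPKM across replicates; ties break toward
    the greater spliced length, then the lexicographically smaller
    transcript id — a total order, so output is deterministic.
    """
    chosen = []
    for gene_id, isoforms in group_by_gene(transcripts).items():
        best = max(
            isoforms,
            key=lambda t: (
                expr.mean_fpkm(t.transcript_id),
                t.spliced_length,
                _neg_lex(t.transcript_id),
            ),
        )
        chosen.append(best)
    return chosen


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def annotate_novelty(
    transcripts: Sequence[TranscriptModel],
    reference: Optional[Iterable[GeneModel]] = None,
) -> tuple[list[TranscriptModel], int]:
    """Set novelty per transcript; drop candidates that are neither novel nor
    annotated non-coding.

    With assembler class codes present: codes ``-``/``x``/``u`` mark novel
    transcripts (unknown intergenic / opposite-strand exonic overlap);
    any other code is annotated iff the attached biotype is a long
    non-coding class, otherwise the transcript is not a lncRNA candidate
    and is dropped (counted). Without class codes a reference annotation is
    required: a transcript is annotated iff its intron chain exactly
    matches a reference non-coding transcript on the same strand
    (monoexonic: >= 50% reciprocal span overlap with a reference
    monoexonic non-coding transcript); otherwise novel.

    Returns (annotated transcripts, number dropped as non-lncRNA).
    """
    have_codes = any(t.class_code is not None for t in transcripts)
    if not have_codes and reference is None and len(transcripts) > 0:
        raise ConfigError(
            "novelty annotation needs either class_code attributes or a reference"
        )

    ref_chains: set[tuple] = set()
    ref_mono: dict[tuple[str, str], list[GenomicInterval]] = {}
    if reference is not None:
        for gene in reference:
            if gene.biotype not in LNC_BIOTYPES:
                continue
            for rt in gene.transcripts:
                if rt.is_monoexonic:
                    ref_mono.setdefault((rt.chrom, rt.strand), []).append(rt.span)
                else:
                    ref_chains.add((rt.chrom, rt.strand, rt.intron_chain()))

    kept: list[TranscriptModel] = []
    dropped = 0
    for t in transcripts:
        if t.class_code is not None:
            if t.class_code in NOVEL_CLASS_CODES:
                t.novelty = NOVELTY_NOVEL
                kept.append(t)
            elif t.biotype in LNC_BIOTYPES:
                t.novelty = NOVELTY_ANNOTATED
                kept.append(t)
            else:
                dropped += 1
            continue
        # fallback: reference comparison
        if t.is_monoexonic:
            span = t.span
            annotated = any(
                span.overlap_length(r) >= 0.5 * span.length
                and span.overlap_length(r) >= 0.5 * r.length
                for key in _strand_keys(t)
                for r in ref_mono.get(key, [])
            )
        else:
            annotated = any(
                (t.chrom, s, t.intron_chain()) in ref_chains for s in _strands_of(t)
            )
        t.novelty = NOVELTY_ANNOTATED if annotated else NOVELTY_NOVEL
        kept.append(t)
    return kept, dropped


def _strands_of(t: TranscriptModel) -> tuple[str, ...]:
    if t.strand == STRAND_UNKNOWN:
        return ("+", "-")
    return (t.strand,)


def _strand_keys(t: TranscriptModel) -> tuple[tuple[str, str], ...]:
    return tuple((t.chrom, s) for s in _strands_of(t))


# ---------------------------------------------------------------------------
# the full procedure
# ---------------------------------------------------------------------------


def build_repertoire(
    transcripts: Sequence[TranscriptModel],
    expr: ExpressionTable,
    scores: dict[str, float],
    consensus_peaks: Sequence[GenomicInterval],
    reference: Sequence[GeneModel],
    config: PipelineConfig = PipelineConfig(),
    cell_type: str = "",
    rules: Optional[ClassificationRules] = None,
) -> Repertoire:
    """Run the full lncRNA selection procedure for one cell type.

    Filter order: length -> expression -> coding potential -> proximity ->
    TSS support / monoexonic rule -> major isoform -> novelty ->
    positional classification. Per-stage drop counts land in the
    repertoire provenance.
    """
    if rules is None:
        rules = ClassificationRules(neighborhood_bp=config.proximity_bp)
    coding_genes = [g for g in reference if g.is_coding]
    drops: dict[str, int] = {}
    current = list(transcripts)
    n_input = len(current)

    for stage, fn in (
        ("length", lambda ts: filter_length(ts, config)),
        ("expression", lambda ts: filter_expression(ts, expr, config)),
        ("coding_potential", lambda ts: filter_coding_potential(ts, scores, config)),
        ("proximity", lambda ts: filter_proximity(ts, coding_genes, config)),
    ):
        survivors = fn(current)
        drops[stage] = len(current) - len(survivors)
        current = survivors

    tss_flags = mark_tss_support(current, consensus_peaks)
    survivors = apply_monoexonic_rule(current, tss_flags)
    drops["monoexonic_no_tss_peak"] = len(current) - len(survivors)
    current = survivors

    survivors = select_major_isoform(current, expr)
    drops["minor_isoform"] = len(current) - len(survivors)
    current = survivors

    current, n_non_lnc = annotate_novelty(current, reference)
    drops["novelty"] = n_non_lnc

    index = GeneIndex(coding_genes)
    entries = []
    for t in sorted(current, key=lambda t: t.transcript_id):
        links = find_closest_genes(t, index)
        entries.append(
            RepertoireEntry(
                transcript=t,
                mean_fpkm=expr.mean_fpkm(t.transcript_id),
                novelty=t.novelty,
                tss_has_peak=tss_flags[t.transcript_id],
                category=classify(t, links, rules),
                links=links,
            )
        )

    rep = Repertoire(
        cell_type=cell_type,
        entries=entries,
        config=config,
        drop_counts=drops,
        n_input=n_input,
    )
    logger.info(
        "build_repertoire(%s): %d -> %d entries; drops %s",
        cell_type,
        n_input,
        len(entries),
        drops,
    )
    assert n_input == len(entries) + sum(drops.values())
    return rep
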