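"""Consensus open-chromatin maps, feature annotation and specificity partition.

A condition's consensus is built from its replicate peak sets: peaks closer
than the merge distance are first merged within each replicate, the pooled
peaks of all replicates are merged into candidate regions, and a candidate
is retained iff it overlaps (by >= 1 bp) at least one peak from *every*
replicate. Cross-condition specificity is then decided per consensus peak
against the *other* condition's replicate peaks: overlapping none of them
makes the peak condition-specific, overlapping all of them makes it common,
and overlapping only some replicates excludes it from the stringent
partition (reported separately).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConfigError,
    GeneModel,
    GenomicInterval,
    PeakCollection,
    PipelineConfig,
    STRAND_MINUS,
    STRAND_PLUS,
    ValidationError,
)
from .repertoire import Repertoire

logger = logging.getLogger("lncrep")

FEATURE_CLASSES = ("promoter", "exon", "tts_3utr_other", "intron", "intergenic")


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bp: int = 0
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals separated by a gap < ``merge_bp``.

    The distance criterion is strict: a gap of exactly ``merge_bp`` does
    not merge. Overlapping intervals always merge; with ``merge_bp=0``
    only overlapping intervals do. Idempotent and order-independent.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end or iv.start - cur_end < merge_bp:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def merge_close_peaks(
    collection: PeakCollection, config: PipelineConfig = PipelineConfig()
) -> PeakCollection:
    """Merge a replicate's peaks separated by less than ``peak_merge_bp``."""
    merged = merge_intervals(collection.peaks, config.peak_merge_bp)
    return PeakCollection(
        condition=collection.condition, replicate=collection.replicate, peaks=merged
    )


class _IntervalIndex:
    """Sorted per-chromosome intervals answering >=1 bp overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda p: (p.start, p.end))
            starts = [p.start for p in ivs]
            ends = [p.end for p in ivs]
            running = np.maximum.accumulate(ends).tolist()
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._maxend[chrom] = running

    def overlaps(self, query: GenomicInterval) -> bool:
        starts = self._starts.get(query.chrom)
        if not starts:
            return False
        i = bisect.bisect_left(starts, query.end)  # intervals starting before query.end
        if i == 0:
            return False
        return self._maxend[query.chrom][i - 1] > query.start


@dataclass
class ConsensusPeakSet:
    """Non-overlapping consensus peaks of one condition with replicate support."""

    condition: str
    peaks: list[GenomicInterval]
    support: list[tuple[str, ...]] = field(default_factory=list)
    replicates: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.peaks)


def _intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for ivl in b:
        by_chrom_b.setdefault(ivl.chrom, []).append(ivl)
    out: list[GenomicInterval] = []
    for chrom in sorted({ivl.chrom for ivl in a}):
        lhs = sorted((ivl for ivl in a if ivl.chrom == chrom), key=lambda p: p.start)
        rhs = sorted(by_chrom_b.get(chrom, []), key=lambda p: p.start)
        i = j = 0
        while i < len(lhs) and j < len(rhs):
            lo = max(lhs[i].start, rhs[j].start)
            hi = min(lhs[i].end, rhs[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if lhs[i].end <= rhs[j].end:
                i += 1
            else:
                j += 1
    return out


def consensus_across_replicates(
    collections: Sequence[PeakCollection],
    config: PipelineConfig = PipelineConfig(),
    premerged: bool = False,
    mode: str = "union",
) -> ConsensusPeakSet:
    """Peaks present simultaneously in every replicate of a condition.

    In the default ``union`` mode candidate regions are the merged union of
    all replicates' peaks and a candidate is retained iff it overlaps at
    least one peak from each replicate (per-region counting; support
    bookkeeping stays simple). ``intersection`` mode instead returns the
    base-level core covered by every replicate, which is anti-monotone in
    the number of replicates. With a single replicate both modes are the
    identity on its merged peaks.
    """
    if not collections:
        raise ConfigError("consensus needs >= 1 replicate peak collection")
    if mode not in ("union", "intersection"):
        raise ConfigError(f"unknown consensus mode {mode!r}")
    if not premerged:
        collections = [merge_close_peaks(c, config) for c in collections]
    if mode == "intersection":
        core = list(collections[0].peaks)
        for c in collections[1:]:
            core = _intersect_two(core, c.peaks)
        return ConsensusPeakSet(
            condition=collections[0].condition,
            peaks=sorted(core, key=lambda p: (p.chrom, p.start)),
            support=[tuple(c.replicate for c in collections) for _ in core],
            replicates=tuple(c.replicate for c in collections),
        )
    pooled = [p for c in collections for p in c.peaks]
    if not pooled:
        return ConsensusPeakSet(
            condition=collections[0].condition,
            peaks=[],
            support=[],
            replicates=tuple(c.replicate for c in collections),
        )
    candidates = merge_intervals(pooled, config.peak_merge_bp)
    indexes = [(_IntervalIndex(c.peaks), c.replicate) for c in collections]
    peaks: list[GenomicInterval] = []
    support: list[tuple[str, ...]] = []
    for cand in candidates:
        present = tuple(rep for idx, rep in indexes if idx.overlaps(cand))
        if len(present) == len(collections):
            peaks.append(cand)
            support.append(present)
    result = ConsensusPeakSet(
        condition=collections[0].condition,
        peaks=peaks,
        support=support,
        replicates=tuple(c.replicate for c in collections),
    )
    logger.info(
        "consensus(%s): %d candidates -> %d consensus peaks",
        result.condition,
        len(candidates),
        len(peaks),
    )
    return result


@dataclass
class PeakPartition:
    """Cross-condition specificity partition of two consensus peak sets.

    Per side the classes are disjoint and additive:
    ``|specific| + |common| + |excluded_partial| = |consensus|``. The
    common class is counted once per side (overlap does not imply a 1:1
    peak pairing); reporting reconciles the two counts.
    """

    condition_a: str
    condition_b: str
    a_specific: list[GenomicInterval] = field(default_factory=list)
    b_specific: list[GenomicInterval] = field(default_factory=list)
    common_a: list[GenomicInterval] = field(default_factory=list)
    common_b: list[GenomicInterval] = field(default_factory=list)
    excluded_a_partial: list[GenomicInterval] = field(default_factory=list)
    excluded_b_partial: list[GenomicInterval] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "a_specific": len(self.a_specific),
            "b_specific": len(self.b_specific),
            "common_a": len(self.common_a),
            "common_b": len(self.common_b),
            "excluded_a_partial": len(self.excluded_a_partial),
            "excluded_b_partial": len(self.excluded_b_partial),
        }


def partition_by_condition(
    consensus_a: ConsensusPeakSet,
    replicates_a: Sequence[PeakCollection],
    consensus_b: ConsensusPeakSet,
    replicates_b: Sequence[PeakCollection],
) -> PeakPartition:
    """Classify each consensus peak by presence in the other condition's
    replicate datasets (>= 1 bp overlap = present)."""
    part = PeakPartition(condition_a=consensus_a.condition, condition_b=consensus_b.condition)

    def side(
        consensus: ConsensusPeakSet,
        other_reps: Sequence[PeakCollection],
        specific: list,
        common: list,
        excluded: list,
    ) -> None:
        idxs = [_IntervalIndex(c.peaks) for c in other_reps]
        for peak in consensus.peaks:
            n = sum(1 for idx in idxs if idx.overlaps(peak))
            if n == 0:
                specific.append(peak)
            elif n == len(other_reps):
                common.append(peak)
            else:
                excluded.append(peak)

    side(consensus_a, replicates_b, part.a_specific, part.common_a, part.excluded_a_partial)
    side(consensus_b, replicates_a, part.b_specific, part.common_b, part.excluded_b_partial)
    logger.info("partition %s vs %s: %s", part.condition_a, part.condition_b, part.counts())
    return part


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


@dataclass
class FeatureAnnotation:
    """One feature label (and gene when applicable) per consensus peak."""

    peaks: list[GenomicInterval]
    features: list[str]
    gene_ids: list[Optional[str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "feature": self.features,
                "gene_id": self.gene_ids,
            }
        )

    def counts(self) -> dict[str, int]:
        out = {f: 0 for f in FEATURE_CLASSES}
        for f in self.features:
            out[f] += 1
        return out


def _oriented_window(
    chrom: str, pos: int, strand: str, upstream: int, downstream: int
) -> GenomicInterval:
    """Bases at oriented distance [-upstream, +downstream) from a position."""
    if strand == STRAND_MINUS:
        start, end = pos - downstream + 1, pos + upstream + 1
    else:
        start, end = pos - upstream, pos + downstream
    return GenomicInterval(chrom, max(0, start), max(max(0, start) + 1, end))


def annotate_features(
    consensus: ConsensusPeakSet,
    reference: Sequence[GeneModel],
    config: PipelineConfig = PipelineConfig(),
) -> FeatureAnnotation:
    """Assign each peak a single genomic feature at its midpoint.

    Precedence: promoter > exon > TTS/3'UTR ("others") > intron >
    intergenic. The promoter window is strand-oriented
    [TSS - upstream_bp, TSS + downstream_bp); the TTS window mirrors it
    downstream of the TTS. Midpoint assignment keeps the percentages of a
    peak set summing to 100.
    """
    up, down = config.promoter_window
    promoters: list[tuple[GenomicInterval, str]] = []
    tts_windows: list[tuple[GenomicInterval, str]] = []
    exons: list[tuple[GenomicInterval, str]] = []
    spans: list[tuple[GenomicInterval, str]] = []
    for gene in reference:
        for t in gene.transcripts:
            if t.strand in (STRAND_PLUS, STRAND_MINUS):
                promoters.append(
                    (_oriented_window(t.chrom, t.tss, t.strand, up, down), gene.gene_id)
                )
                tts_windows.append(
                    (_oriented_window(t.chrom, t.tts, t.strand, down, up), gene.gene_id)
                )
            for e in t.exons:
                exons.append((e, gene.gene_id))
            spans.append((t.span, gene.gene_id))

    layers = [
        ("promoter", _GeneIntervalIndex(promoters)),
        ("exon", _GeneIntervalIndex(exons)),
        ("tts_3utr_other", _GeneIntervalIndex(tts_windows)),
        ("intron", _GeneIntervalIndex(spans)),
    ]
    features: list[str] = []
    gene_ids: list[Optional[str]] = []
    for peak in consensus.peaks:
        mid = peak.midpoint
        label, gid = "intergenic", None
        for name, index in layers:
            hit = index.lookup(peak.chrom, mid)
            if hit is not None:
                label, gid = name, hit
                break
        features.append(label)
        gene_ids.append(gid)
    return FeatureAnnotation(peaks=list(consensus.peaks), features=features, gene_ids=gene_ids)


class _GeneIntervalIndex:
    """Point query over labelled intervals; smallest gene id wins ties."""

    def __init__(self, labelled: Iterable[tuple[GenomicInterval, str]]):
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, gid in labelled:
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
        for lst in self._by_chrom.values():
            lst.sort()

    def lookup(self, chrom: str, pos: int) -> Optional[str]:
        best: Optional[str] = None
        for start, end, gid in self._by_chrom.get(chrom, ()):
            if start > pos:
                break
            if pos < end and (best is None or gid < best):
                best = gid
        return best


# ---------------------------------------------------------------------------
# lncRNA TSS intersection and TSS profiles
# ---------------------------------------------------------------------------


def peaks_at_lnc_tss(
    peaks: Sequence[GenomicInterval], repertoire: Repertoire
) -> pd.DataFrame:
    """Pairs (peak, lncRNA) where the peak contains the lncRNA's TSS base.

    Returns one row per pair with the lncRNA's category and novelty, ready
    for the category/novelty summary of condition-specific peaks.
    """
    index = _GeneIntervalIndex(
        ((p, f"{p.chrom}:{p.start}-{p.end}") for p in peaks)
    )
    rows = []
    for entry in repertoire.entries:
        t = entry.transcript
        for pos in t.candidate_tss_positions():
            hit = index.lookup(t.chrom, pos)
            if hit is not None:
                rows.append(
                    {
                        "peak": hit,
                        "transcript_id": t.transcript_id,
                        "category": entry.category,
                        "novelty": entry.novelty,
                    }
                )
                break
    return pd.DataFrame(rows, columns=["peak", "transcript_id", "category", "novelty"])


def tss_profile(
    peaks: Sequence[GenomicInterval],
    tss_list: Sequence[tuple[str, int, str]],
    window_bp: int,
    bin_bp: int,
) -> np.ndarray:
    """Per-TSS binned peak coverage around each TSS (rows) over bins (cols).

    The window is centred on the TSS; each cell holds the fraction of the
    bin covered by peaks. Rows are strand-oriented so upstream is always on
    the left (minus-strand rows are reversed).
    """
    if window_bp % bin_bp != 0 or (window_bp // bin_bp) % 2 != 0:
        raise ValidationError("window_bp must be an even multiple of bin_bp")
    n_bins = window_bp // bin_bp
    half = window_bp // 2
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    matrix = np.zeros((len(tss_list), n_bins))
    for row, (chrom, pos, strand) in enumerate(tss_list):
        win_start = pos - half
        for p in by_chrom.get(chrom, ()):
            lo = max(p.start, win_start)
            hi = min(p.end, pos + half)
            if lo >= hi:
                continue
            first_bin = (lo - win_start) // bin_bp
            last_bin = (hi - 1 - win_start) // bin_bp
            for b in range(first_bin, last_bin + 1):
                bin_lo = win_start + b * bin_bp
                bin_hi = bin_lo + bin_bp
                covered = min(hi, bin_hi) - max(lo, bin_lo)
                matrix[row, b] += covered / bin_bp
        if strand == STRAND_MINUS:
            matrix[row] = matrix[row, ::-1]
    np.clip(matrix, 0.0, 1.0, out=matrix)
    return matrix
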