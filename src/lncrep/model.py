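"""Core genomic data model shared by every pipeline stage.

All internal coordinates are 0-based half-open (BED convention). GTF I/O
converts 1-based closed coordinates at the boundary and nowhere else.
Strand is one of ``+``, ``-`` or ``.`` (unknown); asking for the TSS/TTS of a
strand-unknown transcript raises :class:`StrandUnknownError` rather than
guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_UNKNOWN = "."
VALID_STRANDS = (STRAND_PLUS, STRAND_MINUS, STRAND_UNKNOWN)

NOVELTY_ANNOTATED = "annotated"
NOVELTY_NOVEL = "novel"
NOVELTY_UNDETERMINED = "undetermined"

#: positional categories of a lncRNA relative to protein-coding genes
CATEGORIES = ("intergenic", "divergent", "convergent", "overlapping_antisense")

#: biotypes counting as "long non-coding" in reference annotation
LNC_BIOTYPES = frozenset({"lncRNA", "antisense", "non_coding"})

#: assembler class codes marking a transcript as unannotated
NOVEL_CLASS_CODES = frozenset({"-", "x", "u", "−"})


class ValidationError(ValueError):
    """Input violates a documented contract."""


class StrandUnknownError(ValidationError):
    """TSS/TTS requested for a transcript whose strand is unknown."""


class ConfigError(ValueError):
    """Pipeline configuration is inconsistent with the supplied data."""


def opposite_strand(strand: str) -> str:
    if strand == STRAND_PLUS:
        return STRAND_MINUS
    if strand == STRAND_MINUS:
        return STRAND_PLUS
    raise StrandUnknownError("unknown strand has no opposite")


def strands_compatible(a: str, b: str) -> bool:
    """True when two strands could be the same (unknown matches anything)."""
    return a == b or STRAND_UNKNOWN in (a, b)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        """Containment of a single base (half-open: ``end`` is excluded)."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap(self, other: "GenomicInterval") -> int:
        """Gap in bp between two same-chromosome intervals; 0 when overlapping."""
        if self.chrom != other.chrom:
            raise ValidationError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_locus(cls, locus: str, strand: str = STRAND_UNKNOWN) -> "GenomicInterval":
        chrom, _, rest = locus.partition(":")
        start, _, end = rest.partition("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass
class TranscriptModel:
    """One assembled transcript: an exon chain on a strand, in a locus group."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    biotype: Optional[str] = None
    class_code: Optional[str] = None
    novelty: str = NOVELTY_UNDETERMINED

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise ValidationError(
                    f"{self.transcript_id}: exon on {exon.chrom}, transcript on {self.chrom}"
                )
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start <= left.end:
                raise ValidationError(
                    f"{self.transcript_id}: exons {left.locus} and {right.locus} "
                    "overlap or touch (need >= 1 bp intron)"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """5'-most transcribed base (position of the single TSS nucleotide)."""
        if self.strand == STRAND_PLUS:
            return self.exons[0].start
        if self.strand == STRAND_MINUS:
            return self.exons[-1].end - 1
        raise StrandUnknownError(f"{self.transcript_id}: TSS undefined, strand unknown")

    @property
    def tts(self) -> int:
        """3'-most transcribed base."""
        if self.strand == STRAND_PLUS:
            return self.exons[-1].end - 1
        if self.strand == STRAND_MINUS:
            return self.exons[0].start
        raise StrandUnknownError(f"{self.transcript_id}: TTS undefined, strand unknown")

    def candidate_tss_positions(self) -> tuple[int, ...]:
        """TSS base, or both span endpoints when the strand is unknown.

        A non-stranded library leaves unannotated monoexonic transcripts
        without orientation; either span end may be the true start, so open
        chromatin at either endpoint counts as TSS support.
        """
        if self.strand == STRAND_UNKNOWN:
            span = self.span
            return (span.start, span.end - 1)
        return (self.tss,)

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (left.end, right.start) for left, right in zip(self.exons, self.exons[1:])
        )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    biotype: Optional[str]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass
class ExpressionTable:
    """Transcript x replicate FPKM matrix for one cell type.

    Missing transcripts queried through :meth:`values` are all-zero rows; the
    quantification itself (FPKM) is an input, never recomputed here.
    """

    data: pd.DataFrame
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValidationError("expression table needs >= 1 replicate column")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate transcript ids in expression table: {dups}")
        if (self.data.values < 0).any():
            raise ValidationError("negative FPKM values in expression table")

    @property
    def n_replicates(self) -> int:
        return self.data.shape[1]

    @property
    def replicates(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def values(self, transcript_id: str) -> np.ndarray:
        if transcript_id in self.data.index:
            return self.data.loc[transcript_id].to_numpy(dtype=float)
        return np.zeros(self.n_replicates)

    def mean_fpkm(self, transcript_id: str) -> float:
        return float(self.values(transcript_id).mean())


@dataclass
class PeakCollection:
    """One replicate's open-chromatin intervals for one condition (strandless)."""

    condition: str
    replicate: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the repertoire/chromatin pipeline.

    Defaults reproduce the published procedure: >= 200 bp spliced length,
    FPKM >= 1 in at least one of three replicates with at least two non-null
    values, CPAT coding-potential cutoff 0.44, 1-kb same-strand proximity
    elimination, 100-bp peak merging, and 90% reciprocal overlap with
    50/500 bp internal/outer exon tolerances for isoform correspondence.
    """

    min_spliced_length: int = 200
    min_fpkm: float = 1.0
    min_detected_replicates: int = 1
    min_nonzero_replicates: int = 2
    coding_cutoff: float = 0.44
    proximity_bp: int = 1000
    peak_merge_bp: int = 100
    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 100
    reciprocal_overlap_frac: float = 0.90
    internal_exon_tol_bp: int = 50
    outer_exon_tol_bp: int = 500
    stranded_library: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_spliced_length",
            "min_fpkm",
            "min_detected_replicates",
            "min_nonzero_replicates",
            "coding_cutoff",
            "proximity_bp",
            "peak_merge_bp",
            "promoter_upstream_bp",
            "promoter_downstream_bp",
            "internal_exon_tol_bp",
            "outer_exon_tol_bp",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.reciprocal_overlap_frac <= 1):
            raise ConfigError("reciprocal_overlap_frac must be in (0, 1]")

    @property
    def promoter_window(self) -> tuple[int, int]:
        return (self.promoter_upstream_bp, self.promoter_downstream_bp)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def transcripts_of(genes: Iterable[GeneModel]) -> list[TranscriptModel]:
    """Flatten gene models into their member transcripts."""
    out: list[TranscriptModel] = []
    for g in genes:
        out.extend(g.transcripts)
    return out


def group_by_gene(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    groups: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        groups.setdefault(t.gene_id, []).append(t)
    return groups
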