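"""Positional classification of lncRNAs relative to protein-coding genes.

Every repertoire entry receives exactly one of four categories:

``overlapping_antisense``
    span intersects a coding gene on the opposite strand;
``divergent``
    no overlap, nearest opposite-strand coding gene within the neighborhood
    window on the lncRNA's 5' side (head-to-head orientation);
``convergent``
    same, but on the 3' side (tail-to-tail);
``intergenic``
    nearest coding gene farther than the neighborhood window on either
    strand.

Same-strand neighbours inside the window cannot occur in a built repertoire
(the proximity filter removed them); strand-unknown survivors are
necessarily beyond the window and classify as intergenic. Precedence is
overlap > divergent/convergent > intergenic; with qualifying genes on both
sides the nearer wins and an exact tie resolves to divergent
(promoter-sharing being the salient case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import (
    GeneModel,
    STRAND_MINUS,
    STRAND_PLUS,
    STRAND_UNKNOWN,
    TranscriptModel,
    ValidationError,
)


@dataclass
class ClassificationRules:
    #: bp window within which an opposite-strand gene makes a lncRNA
    #: divergent/convergent; beyond it the lncRNA is intergenic
    neighborhood_bp: int = 1000

    def __post_init__(self) -> None:
        if self.neighborhood_bp < 0:
            raise ValidationError("neighborhood_bp must be >= 0")


@dataclass(frozen=True)
class GeneLink:
    gene_id: str
    distance: int
    strand: str


@dataclass(frozen=True)
class ClosestGenes:
    """Nearest coding genes left (upstream in genome coordinates), right
    (downstream), and any overlapped gene; distances are span-gap bp."""

    upstream: Optional[GeneLink] = None
    downstream: Optional[GeneLink] = None
    overlapped: Optional[GeneLink] = None


class GeneIndex:
    """Per-chromosome list of coding gene spans for closest-gene queries.

    Linear scan per chromosome; gene counts per chromosome are small at the
    scales this pipeline handles (annotation spans, not reads).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.span.start, g.gene_id))

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)


def find_closest_genes(
    transcript: TranscriptModel, index: GeneIndex
) -> ClosestGenes:
    """Locate the nearest coding genes on each side plus any overlapped gene.

    Distances are gaps between spans (0 = overlap). Ties break toward the
    smaller gene start, making the result a total order.
    """
    span = transcript.span
    best_up: Optional[tuple[int, int, GeneModel]] = None
    best_down: Optional[tuple[int, int, GeneModel]] = None
    best_over: Optional[tuple[int, GeneModel]] = None
    for gene in index.genes_on(transcript.chrom):
        gspan = gene.span
        if gspan.overlaps(span):
            if best_over is None or gspan.start < best_over[0]:
                best_over = (gspan.start, gene)
        elif gspan.end <= span.start:
            gap = span.start - gspan.end
            key = (gap, gspan.start)
            if best_up is None or key < (best_up[0], best_up[1]):
                best_up = (gap, gspan.start, gene)
        else:
            gap = gspan.start - span.end
            key = (gap, gspan.start)
            if best_down is None or key < (best_down[0], best_down[1]):
                best_down = (gap, gspan.start, gene)

    def link(gap: int, gene: GeneModel) -> GeneLink:
        return GeneLink(gene.gene_id, gap, gene.strand)

    return ClosestGenes(
        upstream=link(best_up[0], best_up[2]) if best_up else None,
        downstream=link(best_down[0], best_down[2]) if best_down else None,
        overlapped=link(0, best_over[1]) if best_over else None,
    )


def classify(
    transcript: TranscriptModel,
    links: ClosestGenes,
    rules: ClassificationRules = ClassificationRules(),
) -> str:
    """Assign the positional category for one lncRNA given its gene links."""
    strand = transcript.strand
    if links.overlapped is not None and links.overlapped.strand not in (
        strand,
        STRAND_UNKNOWN,
    ):
        return "overlapping_antisense"

    if strand == STRAND_UNKNOWN:
        # survivors with unknown strand were forced > proximity window from
        # every coding gene upstream; nothing directional can be decided
        return "intergenic"

    def qualifying(link: Optional[GeneLink]) -> Optional[GeneLink]:
        if link is None:
            return None
        if link.distance > rules.neighborhood_bp:
            return None
        if link.strand in (strand, STRAND_UNKNOWN):
            return None  # same-strand neighbours never drive the category
        return link

    left = qualifying(links.upstream)
    right = qualifying(links.downstream)
    # which genomic side is the lncRNA's 5' side
    five_prime_side = "left" if strand == STRAND_PLUS else "right"

    chosen_side: Optional[str] = None
    if left is not None and right is not None:
        if left.distance < right.distance:
            chosen_side = "left"
        elif right.distance < left.distance:
            chosen_side = "right"
        else:
            chosen_side = five_prime_side  # exact tie -> divergent
    elif left is not None:
        chosen_side = "left"
    elif right is not None:
        chosen_side = "right"

    if chosen_side is None:
        return "intergenic"
    return "divergent" if chosen_side == five_prime_side else "convergent"
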