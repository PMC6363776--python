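"""Synthetic two-cell-type datasets with full ground truth.

The generator emulates the study design this pipeline targets: two FACS-like
neuronal cell types, three RNA-seq replicates each, three vs two ATAC-seq
replicates, a stranded library for cell type A and (optionally) a
non-stranded one for cell type B in which unannotated monoexonic transcripts
carry unknown strand. It plants:

* protein-coding genes and lncRNAs of all four positional categories, with
  geometry that makes every planted category valid under the classifier's
  definitions (anchor genes at controlled gaps, inter-locus spacing far
  beyond the 1-kb neighbourhood);
* annotated and novel lncRNAs (class codes and reference biotypes), shared
  isoforms, shared genes with cell-specific isoforms, and cell-specific
  genes;
* decoy transcripts each violating exactly one repertoire rule, labelled
  with the rule they violate;
* ATAC peaks at the TSS of every active transcript with per-replicate width
  and position jitter and optional dropout, plus per-replicate noise peaks,
  condition-specific peaks and deliberately partial peaks, all laid out so
  that distinct peak units can never merge with each other.

All placement is integer-based and driven by one ``numpy`` generator, so a
fixed seed reproduces byte-identical output files.

Ground truth semantics: the truth *repertoires, categories, novelty, pairs
and specificity levels* are the planted intent (noise knobs degrade the
pipeline's recovery of them; at zero noise recovery is exact). The truth
*consensus peaks and partition classes* are derived from the realized peak
intervals, which a correct implementation reproduces exactly at any noise
level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import write_bed, write_expression, write_gtf, write_scores
from .model import (
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    NOVELTY_ANNOTATED,
    NOVELTY_NOVEL,
    PeakCollection,
    PipelineConfig,
    STRAND_MINUS,
    STRAND_PLUS,
    STRAND_UNKNOWN,
    TranscriptModel,
    opposite_strand,
)

CELLS = ("A", "B")

DECOY_RULES = (
    "length",
    "expression_below_min",
    "expression_single_nonzero",
    "coding_potential",
    "proximity",
    "monoexonic_no_peak",
    "non_lnc_biotype",
)


class SpecError(ValueError):
    """Simulation spec is infeasible (e.g. packing does not fit)."""


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    Defaults are the study-like conditions: 3/3 RNA replicates, 3/2 ATAC
    replicates, stranded A / non-stranded B, log-normal FPKM with mild
    replicate noise, well-separated coding/non-coding score distributions
    and TSS-centred ATAC peaks with small jitter.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 4_000_000
    n_coding_genes: int = 60
    n_lnc_per_category: dict = field(
        default_factory=lambda: {
            "intergenic": 12,
            "divergent": 6,
            "convergent": 4,
            "overlapping_antisense": 6,
        }
    )
    frac_monoexonic: float = 0.5
    frac_annotated: float = 0.3
    frac_shared_isoforms: float = 0.2
    frac_shared_genes: float = 0.12
    frac_shared_coding: float = 0.6
    n_minor_isoforms: int = 2
    n_rna_replicates: tuple = (3, 3)
    n_atac_replicates: tuple = (3, 2)
    stranded: tuple = (True, False)
    # expression model (FPKM)
    fpkm_log10_mean: float = 0.7
    fpkm_log10_sd: float = 0.5
    min_active_fpkm: float = 1.5
    replicate_noise_sd: float = 0.15
    p_dropout: float = 0.03
    # coding-potential score model
    noncoding_score_mean: float = 0.12
    coding_score_mean: float = 0.85
    score_concentration: float = 25.0
    misclassification_rate: float = 0.02
    # ATAC peak model
    peak_width_bp: int = 200
    peak_width_sd: float = 20.0
    peak_jitter_bp: int = 10
    p_peak_dropout: float = 0.02
    n_noise_peaks: int = 20
    n_extra_specific_peaks: int = 10
    n_partial_peaks: int = 4
    n_replicate_partial_peaks: int = 3
    include_class_codes: bool = True

    def __post_init__(self) -> None:
        for p in (
            self.frac_monoexonic,
            self.frac_annotated,
            self.frac_shared_isoforms,
            self.frac_shared_genes,
            self.frac_shared_coding,
            self.p_dropout,
            self.misclassification_rate,
            self.p_peak_dropout,
        ):
            if not (0.0 <= p <= 1.0):
                raise SpecError("probabilities/fractions must lie in [0, 1]")
        if min(self.n_rna_replicates) < 1 or min(self.n_atac_replicates) < 1:
            raise SpecError("each cell type needs >= 1 replicate")

    def zero_noise(self) -> "SimulationSpec":
        """Copy with every stochastic degradation switched off."""
        return replace(
            self,
            replicate_noise_sd=0.0,
            p_dropout=0.0,
            misclassification_rate=0.0,
            peak_jitter_bp=0,
            p_peak_dropout=0.0,
        )


@dataclass
class CellTypeData:
    name: str
    stranded: bool
    transcripts: list[TranscriptModel]
    expression: ExpressionTable
    scores: dict[str, float]
    atac_replicates: list[PeakCollection]


@dataclass
class TruthEntry:
    transcript_id: str
    category: str
    novelty: str
    monoexonic: bool
    role: str


@dataclass
class TruthBundle:
    """Planted ground truth for recovery testing."""

    repertoires: dict[str, dict[str, TruthEntry]]
    decoys: dict[str, dict[str, str]]
    consensus: dict[str, list[GenomicInterval]]
    partition: dict[str, list[GenomicInterval]]
    pairs: set[tuple[str, str]]
    specificity: dict[str, dict[str, str]]
    comparison_excluded: dict[str, set[str]]
    coding_frac_specific: dict[str, float]

    def partition_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.partition.items()}


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    reference: list[GeneModel]
    cells: dict[str, CellTypeData]
    truth: TruthBundle
    config: PipelineConfig

    def write(self, outdir) -> None:
        """Emit the exact text formats the pipeline reads, plus truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref_transcripts = [t for g in self.reference for t in g.transcripts]
        write_gtf(ref_transcripts, outdir / "reference.gtf", source="simulated")
        for name, cell in self.cells.items():
            write_gtf(cell.transcripts, outdir / f"{name}.transcripts.gtf", source="simulated")
            write_expression(cell.expression, outdir / f"{name}.expression.tsv")
            write_scores(cell.scores, outdir / f"{name}.scores.tsv")
            for coll in cell.atac_replicates:
                write_bed(coll.peaks, outdir / f"{name}.atac.{coll.replicate}.bed")
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name, entries in self.truth.repertoires.items():
            rows = [
                {
                    "transcript_id": e.transcript_id,
                    "category": e.category,
                    "novelty": e.novelty,
                    "monoexonic": e.monoexonic,
                    "role": e.role,
                }
                for e in sorted(entries.values(), key=lambda e: e.transcript_id)
            ]
            pd.DataFrame(rows).to_csv(
                truth_dir / f"{name}.repertoire.tsv", sep="\t", index=False
            )
        for name, cons in self.truth.consensus.items():
            write_bed(cons, truth_dir / f"{name}.consensus.bed")
        summary = {
            "partition_counts": self.truth.partition_counts(),
            "pairs": sorted(self.truth.pairs),
            "decoys": {c: dict(sorted(d.items())) for c, d in self.truth.decoys.items()},
            "specificity": {
                c: dict(sorted(d.items())) for c, d in self.truth.specificity.items()
            },
            "comparison_excluded": {
                c: sorted(v) for c, v in self.truth.comparison_excluded.items()
            },
            "coding_frac_specific": self.truth.coding_frac_specific,
        }
        with open(truth_dir / "truth.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# internal plan structures
# ---------------------------------------------------------------------------


@dataclass
class _LncPlan:
    uid: str
    category: str
    novelty: str
    monoexonic: bool
    role: str = ""
    transcript: Optional[TranscriptModel] = None  # canonical isoform (neutral ids)
    alt_transcript: Optional[TranscriptModel] = None  # second isoform (shared_gene)
    minor_transcript: Optional[TranscriptModel] = None  # minor isoform (cell A)
    anchor: Optional[GeneModel] = None
    tids: dict = field(default_factory=dict)  # cell -> transcript_id of its isoform


@dataclass
class _PeakUnit:
    """One planted accessible site; realized per condition and replicate."""

    uid: str
    chrom: str
    center: int
    #: (cell, replicate_label) -> realized interval
    realized: dict = field(default_factory=dict)
    #: cells in which the unit is intended present in all replicates
    intended_cells: tuple = ()


class _Layout:
    """Sequential slot placement with generous inter-locus spacing."""

    #: minimum gap between placed loci; far beyond the 1-kb neighbourhood so
    #: planted categories are decided only by their own anchor gene
    GAP = 8000

    def __init__(self, spec: SimulationSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
        self.cursor = {c: 50_000 for c in self.chroms}
        # reserved tail region for standalone peak units
        self.reserved_start = int(spec.chrom_length_bp * 0.8)
        self._reserved_slot = 0

    def place(self, width: int) -> tuple[str, int]:
        chrom = min(self.chroms, key=lambda c: self.cursor[c])
        start = self.cursor[chrom]
        if start + width >= self.reserved_start:
            raise SpecError(
                "infeasible packing: too many loci for chromosome length"
            )
        self.cursor[chrom] = start + width + self.GAP + int(self.rng.integers(0, 4000))
        return chrom, start

    def reserve_peak_site(self) -> tuple[str, int]:
        per_chrom = (self.spec.chrom_length_bp - self.reserved_start - 2000) // 2000
        i = self._reserved_slot
        self._reserved_slot += 1
        chrom = self.chroms[(i // per_chrom) % len(self.chroms)]
        pos = self.reserved_start + 1000 + (i % per_chrom) * 2000
        if i // per_chrom >= len(self.chroms):
            raise SpecError("infeasible packing: reserved peak region exhausted")
        return chrom, pos


def _make_exon_chain(
    chrom: str,
    start: int,
    strand: str,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, length in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def _coding_gene(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    rng: np.random.Generator,
    target_span: Optional[int] = None,
) -> GeneModel:
    n_ex = int(rng.integers(3, 7))
    exon_lens = rng.integers(150, 400, n_ex).tolist()
    if target_span is None:
        intron_lens = rng.integers(500, 1500, n_ex - 1).tolist()
    else:
        # shrink the chain until it fits the requested span (introns >= 300)
        while n_ex > 2 and target_span - sum(exon_lens[:n_ex]) < 300 * (n_ex - 1):
            n_ex -= 1
        exon_lens = exon_lens[:n_ex]
        remaining = target_span - sum(exon_lens)
        base = remaining // (n_ex - 1)
        if base < 300:
            raise SpecError("target gene span too small for exon chain")
        intron_lens = [base] * (n_ex - 1)
        intron_lens[-1] += remaining - base * (n_ex - 1)
    exons = _make_exon_chain(chrom, start, strand, exon_lens, intron_lens)
    transcript = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        biotype="protein_coding",
    )
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        biotype="protein_coding",
        transcripts=[transcript],
    )


def _lnc_exons(
    chrom: str,
    start: int,
    strand: str,
    monoexonic: bool,
    rng: np.random.Generator,
    compact: bool = False,
    n_exons: Optional[int] = None,
) -> tuple[GenomicInterval, ...]:
    if monoexonic:
        return _make_exon_chain(
            chrom, start, strand, [int(rng.integers(300, 1500))], []
        )
    if n_exons is None:
        n_exons = int(rng.integers(2, 5)) if not compact else 2
    if compact:
        exon_lens = rng.integers(200, 400, n_exons).tolist()
        intron_lens = rng.integers(300, 600, n_exons - 1).tolist()
    else:
        exon_lens = rng.integers(200, 600, n_exons).tolist()
        intron_lens = rng.integers(300, 1500, n_exons - 1).tolist()
    return _make_exon_chain(chrom, start, strand, exon_lens, intron_lens)


def _span_of(exons: Sequence[GenomicInterval]) -> int:
    return exons[-1].end - exons[0].start


def _shift_exons(
    exons: Sequence[GenomicInterval], delta: int
) -> tuple[GenomicInterval, ...]:
    return tuple(
        GenomicInterval(e.chrom, e.start + delta, e.end + delta, e.strand)
        for e in exons
    )


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate(spec: SimulationSpec) -> SimulatedDataset:
    """Build one synthetic dataset with ground truth. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    layout = _Layout(spec, rng)
    config = PipelineConfig()

    # ---- lncRNA plans -----------------------------------------------------
    plans: list[_LncPlan] = []
    counter = 0
    for category, count in spec.n_lnc_per_category.items():
        for _ in range(count):
            counter += 1
            plans.append(
                _LncPlan(
                    uid=f"LNC{counter:04d}",
                    category=category,
                    novelty=(
                        NOVELTY_ANNOTATED
                        if rng.random() < spec.frac_annotated
                        else NOVELTY_NOVEL
                    ),
                    monoexonic=rng.random() < spec.frac_monoexonic,
                )
            )

    any_nonstranded = not all(spec.stranded)

    def comparison_safe(p: _LncPlan) -> bool:
        # novel monoexonic non-intergenic transcripts are structurally
        # excluded on a non-stranded side and harmonized away on the other
        if not any_nonstranded:
            return True
        return not (
            p.novelty == NOVELTY_NOVEL
            and p.monoexonic
            and p.category != "intergenic"
        )

    n = len(plans)
    n_shared_iso = int(round(spec.frac_shared_isoforms * n))
    n_shared_gene = int(round(spec.frac_shared_genes * n))
    safe_idx = [i for i, p in enumerate(plans) if comparison_safe(p)]
    unsafe_idx = [i for i, p in enumerate(plans) if not comparison_safe(p)]
    if len(safe_idx) < n_shared_iso + n_shared_gene:
        raise SpecError("not enough comparison-safe lncRNAs for the shared fractions")
    order = rng.permutation(len(safe_idx)).tolist()
    shared_iso_idx = [safe_idx[order[i]] for i in range(n_shared_iso)]
    shared_gene_idx = [
        safe_idx[order[i]] for i in range(n_shared_iso, n_shared_iso + n_shared_gene)
    ]
    rest = [safe_idx[order[i]] for i in range(n_shared_iso + n_shared_gene, len(order))]
    rest += unsafe_idx
    for k, i in enumerate(shared_iso_idx):
        plans[i].role = "shared_isoform"
    for i in shared_gene_idx:
        plans[i].role = "shared_gene"
        plans[i].monoexonic = False  # needs distinct multiexonic isoforms
    for k, i in enumerate(rest):
        plans[i].role = "a_only" if k % 2 == 0 else "b_only"

    # ---- geometry ---------------------------------------------------------
    anchor_counter = 0
    coding_genes: list[GeneModel] = []

    def new_anchor(chrom, start, strand, target_span=None) -> GeneModel:
        nonlocal anchor_counter
        anchor_counter += 1
        return _coding_gene(
            f"CG{anchor_counter:04d}", chrom, start, strand, rng, target_span
        )

    for p in plans:
        n_exons = int(rng.integers(3, 5)) if p.role == "shared_gene" else None
        if p.category == "intergenic":
            exons_rel = _lnc_exons("tmp", 0, STRAND_PLUS, p.monoexonic, rng, n_exons=n_exons)
            width = _span_of(exons_rel)
            chrom, start = layout.place(width)
            strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
            exons = _make_exon_chain(
                chrom, start, strand,
                [e.length for e in exons_rel],
                [b.start - a.end for a, b in zip(exons_rel, exons_rel[1:])],
            )
        elif p.category in ("divergent", "convergent"):
            gene_strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
            strand = opposite_strand(gene_strand)
            exons_rel = _lnc_exons("tmp", 0, strand, p.monoexonic, rng, n_exons=n_exons)
            lnc_width = _span_of(exons_rel)
            if p.category == "divergent":
                gap = int(rng.integers(700, 950))
            else:
                gap = int(rng.integers(250, 950))
            gene_span = int(rng.integers(3000, 6000))
            chrom, start = layout.place(lnc_width + gap + gene_span)
            # divergent: gene TSS faces the lncRNA 5' end across the gap;
            # convergent: gene TTS faces the lncRNA 3' end
            lnc_first = (p.category == "divergent") == (gene_strand == STRAND_PLUS)
            if lnc_first:
                lnc_start, gene_start = start, start + lnc_width + gap
            else:
                gene_start, lnc_start = start, start + gene_span + gap
            p.anchor = new_anchor(chrom, gene_start, gene_strand, target_span=gene_span)
            exons = _make_exon_chain(
                chrom, lnc_start, strand,
                [e.length for e in exons_rel],
                [b.start - a.end for a, b in zip(exons_rel, exons_rel[1:])],
            )
        else:  # overlapping_antisense
            gene_strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
            strand = opposite_strand(gene_strand)
            exons_rel = _lnc_exons(
                "tmp", 0, strand, p.monoexonic, rng, compact=True, n_exons=n_exons
            )
            lnc_width = _span_of(exons_rel)
            gene_span = lnc_width + int(rng.integers(2200, 3200))
            chrom, start = layout.place(gene_span)
            p.anchor = new_anchor(chrom, start, gene_strand, target_span=gene_span)
            # keep the two TSSs well apart so their peaks never merge
            if gene_strand == STRAND_PLUS:
                lnc_start = start + gene_span - lnc_width - 100
            else:
                lnc_start = start + 100
            exons = _make_exon_chain(
                chrom, lnc_start, strand,
                [e.length for e in exons_rel],
                [b.start - a.end for a, b in zip(exons_rel, exons_rel[1:])],
            )
        p.transcript = TranscriptModel(
            transcript_id=p.uid,
            gene_id=f"{p.uid}.g",
            chrom=chrom,
            strand=strand,
            exons=exons,
        )
        if p.anchor is not None:
            coding_genes.append(p.anchor)
        if p.role == "shared_gene":
            # second isoform: drop one internal exon -> different exon count,
            # overlapping locus (same gene, cell-specific isoform)
            internal = int(rng.integers(1, len(exons) - 1))
            alt_exons = tuple(e for j, e in enumerate(exons) if j != internal)
            p.alt_transcript = TranscriptModel(
                transcript_id=f"{p.uid}.alt",
                gene_id=f"{p.uid}.g",
                chrom=chrom,
                strand=strand,
                exons=alt_exons,
            )

    # minor isoforms exercise major-isoform collapsing: same TSS, extended
    # last exon, planted in cell A only, strictly lower expression
    minor_candidates = [
        p
        for p in plans
        if not p.monoexonic
        and p.category == "intergenic"
        and p.role in ("a_only", "shared_isoform")
        and p.alt_transcript is None
    ]
    minor_plans = minor_candidates[: spec.n_minor_isoforms]
    for p in minor_plans:
        exons = p.transcript.exons
        if p.transcript.strand == STRAND_PLUS:
            last = exons[-1]
            new_exons = exons[:-1] + (
                GenomicInterval(last.chrom, last.start, last.end + 400, last.strand),
            )
        else:
            first = exons[0]
            new_exons = (
                GenomicInterval(
                    first.chrom, max(0, first.start - 400), first.end, first.strand
                ),
            ) + exons[1:]
        p.minor_transcript = TranscriptModel(
            transcript_id=f"{p.uid}.minor",
            gene_id=f"{p.uid}.g",
            chrom=p.transcript.chrom,
            strand=p.transcript.strand,
            exons=new_exons,
        )

    # standalone coding genes up to the requested total
    n_standalone = spec.n_coding_genes - anchor_counter
    if n_standalone < 0:
        raise SpecError(
            f"n_coding_genes={spec.n_coding_genes} smaller than the "
            f"{anchor_counter} anchor genes the lncRNA categories require"
        )
    for _ in range(n_standalone):
        span = int(rng.integers(3000, 8000))
        chrom, start = layout.place(span)
        strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        coding_genes.append(new_anchor(chrom, start, strand, target_span=span))

    # coding gene roles (activity per cell type)
    coding_roles: dict[str, str] = {}
    for g in coding_genes:
        r = rng.random()
        if r < spec.frac_shared_coding:
            coding_roles[g.gene_id] = "shared"
        else:
            coding_roles[g.gene_id] = "a_only" if rng.random() < 0.5 else "b_only"
    # anchors stay active everywhere: their open promoters are what the
    # category geometry models
    for p in plans:
        if p.anchor is not None:
            coding_roles[p.anchor.gene_id] = "shared"

    # ---- decoys (per cell type) ------------------------------------------
    decoy_specs: dict[str, list[tuple[str, TranscriptModel, Optional[GeneModel]]]] = {
        c: [] for c in CELLS
    }
    for cell in CELLS:
        for rule in DECOY_RULES:
            if rule == "non_lnc_biotype" and not spec.include_class_codes:
                continue
            anchor = None
            if rule == "length":
                chrom, start = layout.place(150)
                exons = _make_exon_chain(chrom, start, STRAND_PLUS, [150], [])
            elif rule == "monoexonic_no_peak":
                chrom, start = layout.place(800)
                exons = _make_exon_chain(chrom, start, STRAND_PLUS, [800], [])
            elif rule == "proximity":
                gene_span = int(rng.integers(3000, 5000))
                width = gene_span + 400 + 900
                chrom, start = layout.place(width)
                anchor = new_anchor(chrom, start, STRAND_PLUS, target_span=gene_span)
                exons = _make_exon_chain(
                    chrom, start + gene_span + 400, STRAND_PLUS, [400, 300], [200]
                )
            else:
                chrom, start = layout.place(2000)
                exons = _make_exon_chain(chrom, start, STRAND_PLUS, [500, 400], [600])
            tid = f"{cell}_DECOY_{rule}"
            if rule == "non_lnc_biotype":
                biotype, code = "protein_coding", "="
            else:
                biotype = None
                code = "-" if spec.include_class_codes else None
            decoy = TranscriptModel(
                transcript_id=tid,
                gene_id=f"{tid}.g",
                chrom=chrom,
                strand=STRAND_PLUS,
                exons=exons,
                biotype=biotype,
                class_code=code,
            )
            decoy_specs[cell].append((rule, decoy, anchor))
            if anchor is not None:
                coding_genes.append(anchor)
                coding_roles[anchor.gene_id] = "shared"

    # ---- reference annotation --------------------------------------------
    reference: list[GeneModel] = list(coding_genes)
    for p in plans:
        if p.novelty == NOVELTY_ANNOTATED:
            ref_t = TranscriptModel(
                transcript_id=f"REF_{p.uid}",
                gene_id=f"REF_{p.uid}.g",
                chrom=p.transcript.chrom,
                strand=p.transcript.strand,
                exons=p.transcript.exons,
                biotype="lncRNA",
            )
            reference.append(
                GeneModel(
                    gene_id=f"REF_{p.uid}.g",
                    chrom=p.transcript.chrom,
                    strand=p.transcript.strand,
                    biotype="lncRNA",
                    transcripts=[ref_t],
                )
            )
    reference.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))

    # ---- assemble per-cell transcript sets --------------------------------
    def lnc_active_in(p: _LncPlan, cell: str) -> bool:
        if p.role in ("shared_isoform", "shared_gene"):
            return True
        return (p.role == "a_only") == (cell == "A")

    def class_code_for(p: _LncPlan) -> Optional[str]:
        if not spec.include_class_codes:
            return None
        if p.novelty == NOVELTY_ANNOTATED:
            return "="
        return "x" if p.category == "overlapping_antisense" else "-"

    cell_transcripts: dict[str, list[TranscriptModel]] = {c: [] for c in CELLS}
    for ci, cell in enumerate(CELLS):
        stranded = spec.stranded[ci]
        idx = 0
        for p in plans:
            if not lnc_active_in(p, cell):
                continue
            source = (
                p.alt_transcript
                if (p.role == "shared_gene" and cell == "B")
                else p.transcript
            )
            idx += 1
            tid = f"{cell}_TCONS_{idx:05d}"
            p.tids[cell] = tid
            strand = source.strand
            if (
                not stranded
                and p.monoexonic
                and p.novelty == NOVELTY_NOVEL
            ):
                strand = STRAND_UNKNOWN  # non-stranded library: no orientation
            cell_transcripts[cell].append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=f"{cell}_XLOC_{p.uid}",
                    chrom=source.chrom,
                    strand=strand,
                    exons=tuple(
                        GenomicInterval(e.chrom, e.start, e.end, strand)
                        for e in source.exons
                    ),
                    biotype="lncRNA" if p.novelty == NOVELTY_ANNOTATED else None,
                    class_code=class_code_for(p),
                )
            )
            if cell == "A" and p.minor_transcript is not None:
                m = p.minor_transcript
                cell_transcripts[cell].append(
                    TranscriptModel(
                        transcript_id=f"{tid}.m",
                        gene_id=f"{cell}_XLOC_{p.uid}",
                        chrom=m.chrom,
                        strand=m.strand,
                        exons=m.exons,
                        biotype="lncRNA" if p.novelty == NOVELTY_ANNOTATED else None,
                        class_code=class_code_for(p),
                    )
                )
        # active protein-coding transcripts
        for g in coding_genes:
            role = coding_roles[g.gene_id]
            active = role == "shared" or (role == "a_only") == (cell == "A")
            if not active:
                continue
            t = g.transcripts[0]
            cell_transcripts[cell].append(
                TranscriptModel(
                    transcript_id=f"{cell}_{t.transcript_id}",
                    gene_id=f"{cell}_{g.gene_id}",
                    chrom=t.chrom,
                    strand=t.strand,
                    exons=t.exons,
                    biotype="protein_coding",
                    class_code="=" if spec.include_class_codes else None,
                )
            )
        for rule, decoy, _anchor in decoy_specs[cell]:
            cell_transcripts[cell].append(decoy)

    # ---- expression -------------------------------------------------------
    expr_tables: dict[str, ExpressionTable] = {}
    base_fpkm: dict[str, float] = {}  # per realized transcript id
    for ci, cell in enumerate(CELLS):
        n_reps = spec.n_rna_replicates[ci]
        labels = [f"rep{i + 1}" for i in range(n_reps)]
        rows = {}
        for t in cell_transcripts[cell]:
            tid = t.transcript_id
            if tid.endswith("_DECOY_expression_below_min"):
                values = rng.uniform(0.4, 0.95, n_reps)
            elif tid.endswith("_DECOY_expression_single_nonzero"):
                values = np.zeros(n_reps)
                values[0] = 1.8
            else:
                base = 10 ** rng.normal(spec.fpkm_log10_mean, spec.fpkm_log10_sd)
                base = max(base, spec.min_active_fpkm)
                if tid.endswith(".m"):  # minor isoform: strictly below major
                    major = base_fpkm[tid[:-2]]
                    base = max(1.2, min(0.6 * major, major - 0.1))
                base_fpkm[tid] = base
                noise = 10 ** rng.normal(0.0, spec.replicate_noise_sd, n_reps)
                drop = rng.random(n_reps) < spec.p_dropout
                values = np.where(drop, 0.0, base * noise)
            rows[tid] = np.round(values, 4)
        df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
        expr_tables[cell] = ExpressionTable(data=df, cell_type=cell)

    # ---- coding-potential scores ------------------------------------------
    def beta_draw(mean: float, lo: float, hi: float) -> float:
        a = mean * spec.score_concentration
        b = (1 - mean) * spec.score_concentration
        for _ in range(100):
            x = float(rng.beta(a, b))
            if lo <= x <= hi:
                return x
        return float(np.clip(x, lo, hi))

    cutoff = config.coding_cutoff
    score_tables: dict[str, dict[str, float]] = {}
    misclassified: dict[str, set[str]] = {c: set() for c in CELLS}
    for cell in CELLS:
        scores: dict[str, float] = {}
        for t in cell_transcripts[cell]:
            tid = t.transcript_id
            is_codinglike = t.biotype == "protein_coding" and "DECOY" not in tid
            if tid.endswith("_DECOY_coding_potential"):
                scores[tid] = round(beta_draw(spec.coding_score_mean, cutoff + 0.02, 1.0), 4)
            elif tid.endswith("_DECOY_non_lnc_biotype"):
                scores[tid] = round(beta_draw(spec.noncoding_score_mean, 0.0, cutoff - 0.02), 4)
            elif is_codinglike:
                scores[tid] = round(beta_draw(spec.coding_score_mean, cutoff + 0.02, 1.0), 4)
            else:
                if rng.random() < spec.misclassification_rate:
                    scores[tid] = round(
                        beta_draw(spec.coding_score_mean, cutoff + 0.02, 1.0), 4
                    )
                    misclassified[cell].add(tid)
                else:
                    scores[tid] = round(
                        beta_draw(spec.noncoding_score_mean, 0.0, cutoff - 0.02), 4
                    )
        score_tables[cell] = scores

    # ---- ATAC peak units ---------------------------------------------------
    units: list[_PeakUnit] = []

    def add_unit(uid: str, chrom: str, center: int, cells: tuple[str, ...]) -> _PeakUnit:
        u = _PeakUnit(uid=uid, chrom=chrom, center=center, intended_cells=cells)
        units.append(u)
        return u

    # TSS units of active transcripts (decoy monoexonic_no_peak excluded)
    tss_cells: dict[tuple[str, int], set[str]] = {}
    for cell in CELLS:
        for t in cell_transcripts[cell]:
            if t.transcript_id.endswith("_DECOY_monoexonic_no_peak"):
                continue
            if t.strand == STRAND_UNKNOWN:
                # generator knows the true orientation of the planted lncRNA
                plan = next(p for p in plans if p.tids.get(cell) == t.transcript_id)
                tss = plan.transcript.tss
            else:
                tss = t.tss
            tss_cells.setdefault((t.chrom, tss), set()).add(cell)
    for i, ((chrom, tss), cells) in enumerate(sorted(tss_cells.items())):
        add_unit(f"TSS{i:05d}", chrom, tss, tuple(sorted(cells)))

    # standalone units in the reserved region
    for cell in CELLS:
        for k in range(spec.n_extra_specific_peaks):
            chrom, pos = layout.reserve_peak_site()
            add_unit(f"SPEC_{cell}_{k:03d}", chrom, pos, (cell,))
    partial_units: list[tuple[_PeakUnit, str, tuple[str, ...]]] = []
    for ci, cell in enumerate(CELLS):
        other = CELLS[1 - ci]
        n_other = spec.n_atac_replicates[1 - ci]
        for k in range(spec.n_partial_peaks):
            chrom, pos = layout.reserve_peak_site()
            u = add_unit(f"PARTIAL_{cell}_{k:03d}", chrom, pos, (cell,))
            # additionally present in SOME but not all replicates of the
            # other condition -> excluded from the stringent partition
            n_some = 1 + k % max(1, n_other - 1)
            some = tuple(f"atac{j + 1}" for j in range(n_some))
            partial_units.append((u, other, some))
    within_partial: list[tuple[_PeakUnit, str, tuple[str, ...]]] = []
    for ci, cell in enumerate(CELLS):
        n_reps = spec.n_atac_replicates[ci]
        if n_reps < 2:
            continue
        for k in range(spec.n_replicate_partial_peaks):
            chrom, pos = layout.reserve_peak_site()
            u = _PeakUnit(uid=f"REPPART_{cell}_{k:03d}", chrom=chrom, center=pos)
            units.append(u)
            # present in all but one replicate -> absent from consensus
            reps = tuple(f"atac{j + 1}" for j in range(n_reps - 1))
            within_partial.append((u, cell, reps))
    noise_sites: list[tuple[_PeakUnit, str, str]] = []
    for ci, cell in enumerate(CELLS):
        for r in range(spec.n_atac_replicates[ci]):
            for k in range(spec.n_noise_peaks):
                chrom, pos = layout.reserve_peak_site()
                u = _PeakUnit(uid=f"NOISE_{cell}_r{r}_{k:03d}", chrom=chrom, center=pos)
                units.append(u)
                noise_sites.append((u, cell, f"atac{r + 1}"))

    # realize intervals; bounded width/jitter keeps distinct units from merging
    w_lo = max(80, int(spec.peak_width_bp - 4 * spec.peak_width_sd))
    w_hi = int(spec.peak_width_bp + 4 * spec.peak_width_sd)

    def realize(u: _PeakUnit, cell: str, rep: str) -> None:
        width = int(np.clip(round(rng.normal(spec.peak_width_bp, spec.peak_width_sd)), w_lo, w_hi))
        jitter = (
            int(rng.integers(-spec.peak_jitter_bp, spec.peak_jitter_bp + 1))
            if spec.peak_jitter_bp > 0
            else 0
        )
        start = max(0, u.center - width // 2 + jitter)
        u.realized[(cell, rep)] = GenomicInterval(u.chrom, start, start + width)

    for u in units:
        for ci, cell in enumerate(CELLS):
            if cell not in u.intended_cells:
                continue
            for r in range(spec.n_atac_replicates[ci]):
                rep = f"atac{r + 1}"
                if rng.random() < spec.p_peak_dropout:
                    continue
                realize(u, cell, rep)
    for u, other, some in partial_units:
        for rep in some:
            realize(u, other, rep)
    for u, cell, reps in within_partial:
        for rep in reps:
            realize(u, cell, rep)
    for u, cell, rep in noise_sites:
        realize(u, cell, rep)

    atac: dict[str, list[PeakCollection]] = {}
    for ci, cell in enumerate(CELLS):
        colls = []
        for r in range(spec.n_atac_replicates[ci]):
            rep = f"atac{r + 1}"
            peaks = [
                iv for u in units for (c, rp), iv in u.realized.items() if c == cell and rp == rep
            ]
            colls.append(PeakCollection(condition=cell, replicate=rep, peaks=peaks))
        atac[cell] = colls

    cells_data = {
        cell: CellTypeData(
            name=cell,
            stranded=spec.stranded[ci],
            transcripts=cell_transcripts[cell],
            expression=expr_tables[cell],
            scores=score_tables[cell],
            atac_replicates=atac[cell],
        )
        for ci, cell in enumerate(CELLS)
    }

    truth = _build_truth(
        spec, config, plans, decoy_specs, units, cells_data
    )
    return SimulatedDataset(
        spec=spec, reference=reference, cells=cells_data, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# truth assembly
# ---------------------------------------------------------------------------


def _build_truth(
    spec: SimulationSpec,
    config: PipelineConfig,
    plans: list[_LncPlan],
    decoy_specs,
    units: list[_PeakUnit],
    cells_data: dict[str, CellTypeData],
) -> TruthBundle:
    any_nonstranded = not all(spec.stranded)

    def lnc_active_in(p: _LncPlan, cell: str) -> bool:
        if p.role in ("shared_isoform", "shared_gene"):
            return True
        return (p.role == "a_only") == (cell == "A")

    repertoires: dict[str, dict[str, TruthEntry]] = {c: {} for c in CELLS}
    comparison_excluded: dict[str, set[str]] = {c: set() for c in CELLS}
    for ci, cell in enumerate(CELLS):
        stranded = spec.stranded[ci]
        for p in plans:
            if not lnc_active_in(p, cell):
                continue
            structural_drop = (
                not stranded
                and p.novelty == NOVELTY_NOVEL
                and p.monoexonic
                and p.category != "intergenic"
            )
            if structural_drop:
                continue
            tid = p.tids[cell]
            repertoires[cell][tid] = TruthEntry(
                transcript_id=tid,
                category=p.category,
                novelty=p.novelty,
                monoexonic=p.monoexonic,
                role=p.role,
            )
            if (
                any_nonstranded
                and p.novelty == NOVELTY_NOVEL
                and p.monoexonic
                and p.category != "intergenic"
            ):
                comparison_excluded[cell].add(tid)

    decoys = {
        cell: {decoy.transcript_id: rule for rule, decoy, _a in decoy_specs[cell]}
        for cell in CELLS
    }

    # consensus and partition from realized peak units
    consensus: dict[str, list[GenomicInterval]] = {}
    unit_in_consensus: dict[str, dict[str, GenomicInterval]] = {c: {} for c in CELLS}
    for ci, cell in enumerate(CELLS):
        reps = [f"atac{r + 1}" for r in range(spec.n_atac_replicates[ci])]
        out = []
        for u in units:
            ivs = [u.realized.get((cell, rep)) for rep in reps]
            if any(iv is None for iv in ivs):
                continue
            merged = GenomicInterval(
                u.chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
            )
            out.append(merged)
            unit_in_consensus[cell][u.uid] = merged
        out.sort(key=lambda iv: (iv.chrom, iv.start))
        consensus[cell] = out

    partition: dict[str, list[GenomicInterval]] = {
        k: []
        for k in (
            "a_specific",
            "b_specific",
            "common_a",
            "common_b",
            "excluded_a_partial",
            "excluded_b_partial",
        )
    }
    for ci, cell in enumerate(CELLS):
        other = CELLS[1 - ci]
        other_reps = [f"atac{r + 1}" for r in range(spec.n_atac_replicates[1 - ci])]
        side = "a" if cell == "A" else "b"
        by_uid = unit_in_consensus[cell]
        for u in units:
            iv = by_uid.get(u.uid)
            if iv is None:
                continue
            n_other = sum(1 for rep in other_reps if (other, rep) in u.realized)
            if n_other == 0:
                partition[f"{side}_specific"].append(iv)
            elif n_other == len(other_reps):
                partition[f"common_{side}"].append(iv)
            else:
                partition[f"excluded_{side}_partial"].append(iv)

    # planted correspondences and specificity (on comparable sets)
    pairs: set[tuple[str, str]] = set()
    specificity: dict[str, dict[str, str]] = {c: {} for c in CELLS}
    for p in plans:
        in_a = p.tids.get("A") in repertoires["A"]
        in_b = p.tids.get("B") in repertoires["B"]
        comp_a = in_a and p.tids["A"] not in comparison_excluded["A"]
        comp_b = in_b and p.tids["B"] not in comparison_excluded["B"]
        if p.role == "shared_isoform" and comp_a and comp_b:
            pairs.add((p.tids["A"], p.tids["B"]))
            specificity["A"][p.tids["A"]] = "same_gene_same_isoform"
            specificity["B"][p.tids["B"]] = "same_gene_same_isoform"
        elif p.role == "shared_gene" and comp_a and comp_b:
            specificity["A"][p.tids["A"]] = "same_gene_specific_isoform"
            specificity["B"][p.tids["B"]] = "same_gene_specific_isoform"
        else:
            if comp_a:
                specificity["A"][p.tids["A"]] = "specific_gene"
            if comp_b:
                specificity["B"][p.tids["B"]] = "specific_gene"

    # protein-coding truth: fraction of compared transcripts that are
    # specific, decided by exact exon-coordinate identity across cell types
    def exon_key(t: TranscriptModel) -> tuple:
        return (t.chrom, t.strand, tuple((e.start, e.end) for e in t.exons))

    coding_frac: dict[str, float] = {}
    for cell in CELLS:
        own = [
            t for t in cells_data[cell].transcripts if t.biotype == "protein_coding"
        ]
        other_keys = {
            exon_key(t)
            for c2 in CELLS
            if c2 != cell
            for t in cells_data[c2].transcripts
            if t.biotype == "protein_coding"
        }
        if own:
            n_specific = sum(1 for t in own if exon_key(t) not in other_keys)
            coding_frac[cell] = n_specific / len(own)
        else:
            coding_frac[cell] = 0.0

    return TruthBundle(
        repertoires=repertoires,
        decoys=decoys,
        consensus=consensus,
        partition=partition,
        pairs=pairs,
        specificity=specificity,
        comparison_excluded=comparison_excluded,
        coding_frac_specific=coding_frac,
    )


# ---------------------------------------------------------------------------
# fixtures and focused instances
# ---------------------------------------------------------------------------


def make_fixture(name: str, seed: int = 0) -> SimulatedDataset:
    """Pre-parameterized datasets: ``tiny`` for fast unit tests,
    ``paper_like`` for the scaled-down two-cell-type design (3 vs 2 ATAC
    replicates, non-stranded B side, every code path exercised)."""
    if name == "tiny":
        spec = SimulationSpec(
            seed=seed,
            n_chromosomes=1,
            chrom_length_bp=2_500_000,
            n_coding_genes=20,
            n_lnc_per_category={
                "intergenic": 5,
                "divergent": 3,
                "convergent": 2,
                "overlapping_antisense": 2,
            },
            stranded=(True, True),
            n_noise_peaks=8,
            n_extra_specific_peaks=4,
            n_partial_peaks=2,
            n_replicate_partial_peaks=2,
            n_minor_isoforms=1,
        )
    elif name == "paper_like":
        spec = SimulationSpec(
            seed=seed,
            n_chromosomes=2,
            chrom_length_bp=4_000_000,
            n_coding_genes=100,
            n_lnc_per_category={
                "intergenic": 28,
                "divergent": 14,
                "convergent": 6,
                "overlapping_antisense": 12,
            },
            stranded=(True, False),
            n_minor_isoforms=3,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return generate(spec)


def make_correspondence_instance(
    n_pairs: int,
    seed: int,
    jitter: str = "none",
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[TranscriptModel], list[TranscriptModel], set[tuple[str, str]]]:
    """Planted transcript pairs for correspondence-recovery experiments.

    ``jitter='within'`` draws every exon-boundary offset uniformly inside
    the matching tolerances (internal exons within 50 bp, outermost exons
    within 500 bp) with exons long enough that the 90% reciprocal-overlap
    criterion always holds — every pair must be recovered.
    ``jitter='beyond'`` draws each offset in (tol, 2*tol] so every pair
    violates at least one exon tolerance — no pair may be recovered.
    ``jitter='none'`` copies coordinates exactly.
    """
    rng = np.random.default_rng(seed)
    a_list: list[TranscriptModel] = []
    b_list: list[TranscriptModel] = []
    expected: set[tuple[str, str]] = set()
    exon_lens = [12_000, 3_000, 12_000]
    intron_lens = [2_500, 2_500]
    spacing = 40_000
    tol_in = config.internal_exon_tol_bp
    tol_out = config.outer_exon_tol_bp
    for i in range(n_pairs):
        start = 50_000 + i * spacing
        strand = STRAND_PLUS if i % 2 == 0 else STRAND_MINUS
        exons = _make_exon_chain("chr1", start, strand, exon_lens, intron_lens)
        tid_a, tid_b = f"A_P{i:03d}", f"B_P{i:03d}"
        a_list.append(
            TranscriptModel(tid_a, f"{tid_a}.g", "chr1", strand, exons)
        )
        if jitter == "none":
            b_exons = exons
        else:
            b_coords = []
            for rank, e in enumerate(exons):
                tol = tol_out if rank in (0, len(exons) - 1) else tol_in
                if jitter == "within":
                    ds = int(rng.integers(-tol, tol + 1))
                    de = int(rng.integers(-tol, tol + 1))
                else:  # beyond: strictly outside the tolerance
                    ds = int(rng.integers(tol + 1, 2 * tol + 1)) * (
                        -1 if rng.random() < 0.5 else 1
                    )
                    de = int(rng.integers(tol + 1, 2 * tol + 1)) * (
                        -1 if rng.random() < 0.5 else 1
                    )
                b_coords.append((e.start + ds, e.end + de))
            b_exons = tuple(
                GenomicInterval("chr1", s, e, strand) for s, e in b_coords
            )
        b_list.append(
            TranscriptModel(tid_b, f"{tid_b}.g", "chr1", strand, b_exons)
        )
        expected.add((tid_a, tid_b))
    return a_list, b_list, expected
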