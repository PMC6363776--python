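"""End-to-end orchestration over in-memory datasets or files on disk.

Thin glue: each step is a library call; nothing here implements science.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .atac import (
    ConsensusPeakSet,
    FeatureAnnotation,
    PeakPartition,
    annotate_features,
    consensus_across_replicates,
    partition_by_condition,
    peaks_at_lnc_tss,
)
from .compare import CodingComparison, SpecificityResult, compare_protein_coding, compare_repertoires
from .model import GeneModel, PipelineConfig
from .repertoire import Repertoire, build_repertoire
from .simulate import SimulatedDataset


@dataclass
class CellResult:
    repertoire: Repertoire
    consensus: ConsensusPeakSet
    features: FeatureAnnotation


@dataclass
class AnalysisResult:
    cells: dict[str, CellResult]
    partition: PeakPartition
    specificity: SpecificityResult
    coding: CodingComparison
    tss_pairs: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_cell(
    dataset: SimulatedDataset, cell: str, config: Optional[PipelineConfig] = None
) -> CellResult:
    """Consensus open chromatin, repertoire and feature annotation for one cell."""
    data = dataset.cells[cell]
    cfg = (config or dataset.config).replace(stranded_library=data.stranded)
    consensus = consensus_across_replicates(data.atac_replicates, cfg)
    repertoire = build_repertoire(
        transcripts=[t for t in data.transcripts],
        expr=data.expression,
        scores=data.scores,
        consensus_peaks=consensus.peaks,
        reference=dataset.reference,
        config=cfg,
        cell_type=cell,
    )
    features = annotate_features(consensus, dataset.reference, cfg)
    return CellResult(repertoire=repertoire, consensus=consensus, features=features)


def run_all(
    dataset: SimulatedDataset, config: Optional[PipelineConfig] = None
) -> AnalysisResult:
    """The full two-cell-type analysis on a simulated (or loaded) dataset."""
    names = list(dataset.cells)
    a, b = names[0], names[1]
    results = {c: run_cell(dataset, c, config) for c in names}
    partition = partition_by_condition(
        results[a].consensus,
        dataset.cells[a].atac_replicates,
        results[b].consensus,
        dataset.cells[b].atac_replicates,
    )
    coding_genes = [g for g in dataset.reference if g.is_coding]
    specificity = compare_repertoires(
        results[a].repertoire,
        results[b].repertoire,
        coding_genes,
        config or dataset.config,
    )
    coding = compare_protein_coding(
        [t for t in dataset.cells[a].transcripts if t.biotype == "protein_coding"],
        [t for t in dataset.cells[b].transcripts if t.biotype == "protein_coding"],
        dataset.cells[a].expression,
        dataset.cells[b].expression,
        config or dataset.config,
    )
    tss_pairs = {
        a: peaks_at_lnc_tss(partition.a_specific, results[a].repertoire),
        b: peaks_at_lnc_tss(partition.b_specific, results[b].repertoire),
    }
    return AnalysisResult(
        cells=results,
        partition=partition,
        specificity=specificity,
        coding=coding,
        tss_pairs=tss_pairs,
    )
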