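"""Readers and writers for GTF, BED/narrowPeak, TSV tables and YAML config.

GTF coordinates (1-based, closed) are converted to the internal 0-based
half-open convention on read and back on write; the conversion is an exact
bijection and lengths are preserved. Chromosome names are taken verbatim —
no ``chr`` normalization — and a namespace mismatch between two inputs is
reported as a warning listing the symmetric difference.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .model import (
    ConfigError,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    PeakCollection,
    PipelineConfig,
    STRAND_UNKNOWN,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger("lncrep")

PathLike = Union[str, Path]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: PathLike, kind: str = "transcripts") -> list[GeneModel]:
    """Read a GTF file into gene models grouped by ``gene_id``.

    Parameters
    ----------
    path
        GTF file with ``exon`` feature lines carrying ``gene_id`` and
        ``transcript_id`` attributes; ``class_code`` and
        ``gene_biotype``/``transcript_biotype``/``biotype`` are honoured
        when present.
    kind
        ``"transcripts"`` for an assembled transcriptome, ``"reference"``
        for a reference annotation. Parsing is identical; the label only
        affects log messages.
    """
    path = Path(path)
    exon_rows: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: exon end < start")
            attributes = _parse_attributes(attrs)
            try:
                tid = attributes["transcript_id"]
                gid = attributes["gene_id"]
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: missing {exc.args[0]} attribute"
                ) from exc
            if strand not in ("+", "-"):
                strand = STRAND_UNKNOWN
            # GTF 1-based closed -> internal 0-based half-open
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            if tid not in meta:
                order.append(tid)
                biotype = (
                    attributes.get("transcript_biotype")
                    or attributes.get("gene_biotype")
                    or attributes.get("biotype")
                )
                meta[tid] = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": biotype,
                    "class_code": attributes.get("class_code"),
                }
            exon_rows.setdefault(tid, []).append(interval)

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in order:
        m = meta[tid]
        transcript = TranscriptModel(
            transcript_id=tid,
            gene_id=m["gene_id"],
            chrom=m["chrom"],
            strand=m["strand"],
            exons=tuple(exon_rows[tid]),
            biotype=m["biotype"],
            class_code=m["class_code"],
        )
        gid = m["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid, chrom=m["chrom"], strand=m["strand"], biotype=m["biotype"]
            )
            gene_order.append(gid)
        gene = genes[gid]
        gene.transcripts.append(transcript)
        if gene.strand != transcript.strand:
            gene.strand = STRAND_UNKNOWN if gene.transcripts else transcript.strand
        if gene.biotype is None:
            gene.biotype = transcript.biotype
    result = [genes[g] for g in gene_order]
    logger.info(
        "read_gtf(%s, kind=%s): %d genes, %d transcripts",
        path.name,
        kind,
        len(result),
        len(order),
    )
    return result


def write_gtf(
    transcripts: Iterable[TranscriptModel], path: PathLike, source: str = "lncrep"
) -> None:
    """Write transcripts as GTF (1-based closed coordinates on disk)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.class_code is not None:
                attrs += f' class_code "{t.class_code}";'
            if t.biotype is not None:
                attrs += f' biotype "{t.biotype}";'
            span = t.span
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for exon in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_peaks(
    path: PathLike,
    format: str = "bed",
    condition: str = "",
    replicate: str = "",
) -> PeakCollection:
    """Read a BED3+/narrowPeak file into a sorted :class:`PeakCollection`.

    Columns beyond the interval (and optional score) are ignored; an empty
    file yields an empty collection.
    """
    if format not in ("bed", "narrowPeak"):
        raise ConfigError(f"unknown peak format {format!r}")
    path = Path(path)
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            peaks.append(GenomicInterval(fields[0], start, end))
    collection = PeakCollection(condition=condition, replicate=replicate, peaks=peaks)
    logger.info("read_peaks(%s): %d peaks", path.name, len(collection))
    return collection


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: PathLike,
    names: Optional[Sequence[str]] = None,
) -> None:
    intervals = list(intervals)
    if names is not None and len(names) != len(intervals):
        raise ValidationError("names length must match interval count")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_expression(path: PathLike, cell_type: str = "") -> ExpressionTable:
    """Read a transcript x replicate FPKM TSV.

    The header row gives replicate labels; the first column holds transcript
    ids. Blank cells become 0 FPKM (logged); negative values and duplicate
    transcript ids are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate transcript ids {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric FPKM value ({exc})") from exc
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d blank FPKM cells treated as 0", path.name, n_missing)
        df = df.fillna(0.0)
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative FPKM values")
    df.index = df.index.astype(str)
    table = ExpressionTable(data=df, cell_type=cell_type)
    logger.info(
        "read_expression(%s): %d transcripts x %d replicates",
        path.name,
        df.shape[0],
        df.shape[1],
    )
    return table


def write_expression(table: ExpressionTable, path: PathLike) -> None:
    table.data.to_csv(path, sep="\t", float_format="%.4f", index_label="transcript_id")


def read_scores(path: PathLike) -> dict[str, float]:
    """Read a two-column transcript-id -> coding-potential-score TSV.

    A header row is detected and skipped; scores must lie in [0, 1].
    """
    path = Path(path)
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                score = float(fields[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            if not (0.0 <= score <= 1.0):
                raise ValidationError(f"{path}:{lineno}: score {score} outside [0, 1]")
            tid = fields[0]
            if tid in scores:
                raise ValidationError(f"{path}:{lineno}: duplicate transcript id {tid}")
            scores[tid] = score
    logger.info("read_scores(%s): %d transcripts", path.name, len(scores))
    return scores


def write_scores(scores: dict[str, float], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcoding_score\n")
        for tid, score in scores.items():
            fh.write(f"{tid}\t{score:.4f}\n")


def read_config(path: PathLike) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(data)


def write_config(config: PipelineConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def check_chrom_namespaces(names_a: Iterable[str], names_b: Iterable[str]) -> set[str]:
    """Warn when two inputs use different chromosome name sets.

    Returns the symmetric difference (empty when namespaces agree).
    """
    a, b = set(names_a), set(names_b)
    diff = a ^ b
    if diff and a and b:
        logger.warning(
            "chromosome namespace mismatch; symmetric difference: %s", sorted(diff)
        )
    return diff
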