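"""Summary tables aggregating pipeline outputs, with cross-foot checks.

Every table verifies its own arithmetic at build time: category counts sum
to the repertoire size, partition classes sum to each condition's consensus
total, percentage rows sum to 100 (within rounding), and a violation aborts
with the offending table. Percentages are rounded half-away-from-zero, and
raw fractions are always co-emitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .atac import FEATURE_CLASSES, ConsensusPeakSet, FeatureAnnotation, PeakPartition
from .compare import LEVELS, SpecificityResult
from .model import CATEGORIES
from .repertoire import Repertoire


class IntegrityError(ValueError):
    """A summary table failed its cross-foot identity."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3), matching printed-style percents."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percentage(count: int, total: int, ndigits: int = 0) -> float:
    if total == 0:
        return 0.0
    return round_half_away(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def category_novelty_table(repertoire: Repertoire) -> pd.DataFrame:
    """Category x novelty counts of a repertoire, with a verified total row."""
    rows = []
    for cat in CATEGORIES:
        entries = [e for e in repertoire.entries if e.category == cat]
        rows.append(
            {
                "category": cat,
                "annotated": sum(1 for e in entries if e.novelty == "annotated"),
                "novel": sum(1 for e in entries if e.novelty == "novel"),
                "total": len(entries),
            }
        )
    df = pd.DataFrame(rows)
    total = int(df["total"].sum())
    if total != len(repertoire):
        raise IntegrityError(
            f"category counts {df['total'].tolist()} do not sum to repertoire "
            f"size {len(repertoire)}"
        )
    df.loc[len(df)] = {
        "category": "total",
        "annotated": int(df["annotated"].sum()),
        "novel": int(df["novel"].sum()),
        "total": total,
    }
    return df


def specificity_table(result: SpecificityResult) -> pd.DataFrame:
    """Specificity level counts and percentages per side."""
    rows = []
    for side in ("a", "b"):
        counts = result.counts(side)
        total = sum(counts.values())
        for level in LEVELS:
            rows.append(
                {
                    "side": side,
                    "level": level,
                    "count": counts[level],
                    "fraction": counts[level] / total if total else 0.0,
                    "percent": percentage(counts[level], total, 1),
                }
            )
    df = pd.DataFrame(rows)
    for side in ("a", "b"):
        sub = df[df["side"] == side]
        if len(sub) and sub["count"].sum() > 0:
            pct = float(sub["percent"].sum())
            if abs(pct - 100.0) > 0.3:  # three rows rounded to 0.1
                raise IntegrityError(f"specificity percentages for {side} sum to {pct}")
    return df


def partition_table(partition: PeakPartition, consensus_sizes: dict[str, int]) -> pd.DataFrame:
    """Partition class counts per condition with additivity verified.

    ``consensus_sizes`` maps side ('a'/'b') to the consensus peak count the
    classes must sum to.
    """
    counts = partition.counts()
    rows = []
    for side in ("a", "b"):
        spec = counts[f"{side}_specific"]
        common = counts[f"common_{side}"]
        excl = counts[f"excluded_{side}_partial"]
        total = consensus_sizes[side]
        if spec + common + excl != total:
            raise IntegrityError(
                f"partition classes for side {side} sum to {spec + common + excl}, "
                f"consensus has {total}"
            )
        rows.append(
            {
                "side": side,
                "condition": partition.condition_a if side == "a" else partition.condition_b,
                "specific": spec,
                "common": common,
                "excluded_partial": excl,
                "consensus_total": total,
                "specific_fraction": spec / total if total else 0.0,
                "specific_percent": percentage(spec, total),
            }
        )
    return pd.DataFrame(rows)


def feature_table(annotation: FeatureAnnotation) -> pd.DataFrame:
    counts = annotation.counts()
    total = sum(counts.values())
    rows = [
        {
            "feature": f,
            "count": counts[f],
            "fraction": counts[f] / total if total else 0.0,
            "percent": percentage(counts[f], total),
        }
        for f in FEATURE_CLASSES
    ]
    df = pd.DataFrame(rows)
    if total and abs(df["fraction"].sum() - 1.0) > 1e-9:
        raise IntegrityError("feature fractions do not sum to 1")
    return df


def peaks_at_tss_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Category x novelty counts of lncRNAs with a condition-specific peak
    at their TSS."""
    if pairs.empty:
        return pd.DataFrame(columns=["category", "novelty", "count"])
    out = (
        pairs.groupby(["category", "novelty"], dropna=False)
        .size()
        .reset_index(name="count")
    )
    if int(out["count"].sum()) != len(pairs):
        raise IntegrityError("peaks-at-TSS counts do not cross-foot")
    return out


def expression_density_table(
    groups: dict[str, Sequence[float]], eps: float = 1e-3
) -> pd.DataFrame:
    """log10(FPKM) values per transcript class (coding vs lncRNA categories),
    long format for density plotting."""
    rows = []
    for label, values in groups.items():
        for v in values:
            rows.append({"class": label, "log10_fpkm": float(np.log10(max(v, eps)))})
    return pd.DataFrame(rows, columns=["class", "log10_fpkm"])


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------


@dataclass
class SummaryReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {}
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            payload[name] = json.loads(df.to_json(orient="records"))
        with open(outdir / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def summarize(
    repertoires: Optional[dict[str, Repertoire]] = None,
    specificity: Optional[SpecificityResult] = None,
    partition: Optional[PeakPartition] = None,
    consensus: Optional[dict[str, ConsensusPeakSet]] = None,
    features: Optional[dict[str, FeatureAnnotation]] = None,
    tss_pairs: Optional[dict[str, pd.DataFrame]] = None,
    expression_groups: Optional[dict[str, Sequence[float]]] = None,
) -> SummaryReport:
    """Aggregate whatever stage outputs are supplied; empty inputs yield an
    empty report (no error). All cross-foot identities are verified."""
    report = SummaryReport()
    if repertoires:
        for name, rep in repertoires.items():
            report.tables[f"categories_{name}"] = category_novelty_table(rep)
    if specificity is not None:
        report.tables["specificity"] = specificity_table(specificity)
    if partition is not None and consensus is not None:
        sizes = {"a": 0, "b": 0}
        by_condition = {c.condition: len(c) for c in consensus.values()}
        sizes["a"] = by_condition.get(partition.condition_a, 0)
        sizes["b"] = by_condition.get(partition.condition_b, 0)
        report.tables["partition"] = partition_table(partition, sizes)
    if features:
        for name, ann in features.items():
            report.tables[f"features_{name}"] = feature_table(ann)
    if tss_pairs:
        for name, pairs in tss_pairs.items():
            report.tables[f"peaks_at_lnc_tss_{name}"] = peaks_at_tss_table(pairs)
    if expression_groups:
        report.tables["expression_density"] = expression_density_table(expression_groups)
    return report
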