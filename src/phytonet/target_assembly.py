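"""Screening and assembly of the therapeutic target set.

Compound->target predictions (SwissTargetPrediction-style exports with a
probability column) are kept when probability > 0; disease-target tables
(GeneCards/OMIM/DisGeNET/TTD-style, one table per source with a score
column) are screened per source at score >= that source's mean.  The
screened compound union intersected with the merged disease union is the
therapeutic target set consumed by the network stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneSet",
    "ScreenReport",
    "screen_predictions",
    "screen_disease_targets",
    "merge_sources",
    "intersect_targets",
    "read_predictions",
    "read_disease_targets",
    "write_gene_set",
    "read_gene_set",
]


def canonical_gene(symbol: str) -> str:
    """Uppercase, whitespace-stripped gene symbol."""
    sym = str(symbol).strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    return sym


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of canonicalized gene symbols."""

    label: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(canonical_gene(g) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class ScreenReport:
    """Per-stage record of what a screen kept and dropped."""

    stage: str
    thresholds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stage": self.stage, "thresholds": self.thresholds, "counts": self.counts}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def screen_predictions(
    records: pd.DataFrame, probability_threshold: float = 0.0
) -> tuple[dict[str, GeneSet], GeneSet, ScreenReport]:
    """Screen compound->target predictions at probability > threshold.

    Returns the per-compound gene sets, the deduplicated union across
    compounds, and a report with raw / kept / unique counts.
    """
    required = {"compound_id", "gene", "probability"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    probs = pd.to_numeric(records["probability"], errors="coerce")
    bad = records.index[probs.isna() | (probs < 0) | (probs > 1)]
    if len(bad):
        raise ValueError(
            f"probability outside [0, 1] in prediction rows {list(bad[:5])}"
        )
    kept = records.loc[probs > probability_threshold]
    per_compound: dict[str, GeneSet] = {}
    for cid, group in kept.groupby("compound_id", sort=True):
        per_compound[str(cid)] = GeneSet.from_iterable(str(cid), group["gene"])
    union_genes: set[str] = set()
    for gs in per_compound.values():
        union_genes |= gs.genes
    union = GeneSet("compound_union", frozenset(union_genes))
    report = ScreenReport(
        stage="screen_predictions",
        thresholds={"probability_gt": probability_threshold},
        counts={
            "raw": int(len(records)),
            "kept": int(len(kept)),
            "unique_genes": len(union),
            "compounds_with_targets": len(per_compound),
        },
    )
    return per_compound, union, report


def screen_disease_targets(
    records: pd.DataFrame,
) -> tuple[dict[str, GeneSet], ScreenReport]:
    """Screen disease targets per source at score >= the source's mean.

    Duplicate genes within a source collapse to their maximum score before
    the mean is computed.  A source whose score column is entirely blank is
    kept whole (curated databases without a ranking score).
    """
    required = {"source", "gene"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"disease table missing columns: {sorted(missing)}")
    if "score" not in records.columns:
        records = records.assign(score=float("nan"))
    per_source: dict[str, GeneSet] = {}
    counts: dict[str, dict] = {}
    thresholds: dict[str, float | None] = {}
    for source, group in records.groupby("source", sort=True):
        source = str(source)
        scores = pd.to_numeric(group["score"], errors="coerce")
        if scores.notna().any():
            if (~scores.apply(math.isfinite) & scores.notna()).any():
                raise ValueError(f"non-finite score in source {source}")
            if scores.isna().any():
                raise ValueError(f"mixed blank and numeric scores in source {source}")
            genes = group["gene"].map(canonical_gene)
            best = scores.groupby(genes).max()
            mean = float(best.mean())
            kept = best.index[best >= mean]
            thresholds[source] = mean
            counts[source] = {"raw": int(len(group)), "unique": int(len(best)),
                              "kept": int(len(kept))}
        else:
            kept = group["gene"].map(canonical_gene).unique()
            thresholds[source] = None  # no score column: keep all
            counts[source] = {"raw": int(len(group)), "unique": int(len(set(kept))),
                              "kept": int(len(set(kept)))}
        per_source[source] = GeneSet.from_iterable(source, kept)
    report = ScreenReport(
        stage="screen_disease_targets",
        thresholds={"score_ge_mean_per_source": thresholds},
        counts=counts,
    )
    return per_source, report


def merge_sources(per_source: Mapping[str, GeneSet]) -> GeneSet:
    """Union of per-source screened gene sets (duplicates removed)."""
    merged: set[str] = set()
    for gs in per_source.values():
        merged |= gs.genes
    return GeneSet("disease_union", frozenset(merged))


def intersect_targets(compound_union: GeneSet, disease_union: GeneSet) -> GeneSet:
    """The therapeutic target set: compound targets also linked to disease."""
    return GeneSet("therapeutic", compound_union.genes & disease_union.genes)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_disease_targets(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for gene in gene_set:
            fh.write(gene + "\n")


def read_gene_set(path, label: str | None = None) -> GeneSet:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneSet.from_iterable(label or str(path), genes)
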