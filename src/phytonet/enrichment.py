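"""Hypergeometric over-representation analysis (ORA).

For a query gene set of size n drawn against a background of N genes, a term
annotating K genes with k of them in the query is scored with the upper-tail
hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n),

the probability of an overlap at least as large under random draws.  Terms
are screened at raw p < alpha (0.01 by default, no multiple-testing
correction; Benjamini-Hochberg is available behind a flag) and the per-
category top-k selection ranks by enriched gene count, the rule used for
bubble-plot displays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .target_assembly import GeneSet, canonical_gene

CATEGORIES = ("BP", "CC", "MF", "KEGG")

__all__ = [
    "Term",
    "AnnotationDB",
    "EnrichmentRow",
    "ora",
    "select_top",
    "bubble_export",
    "rows_to_frame",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class Term:
    term_id: str
    term_name: str
    category: str  # BP | CC | MF | KEGG
    genes: frozenset[str]


class AnnotationDB:
    """Term -> gene annotation with a background universe.

    The default background is the union of all annotated genes; a custom
    background may be supplied but must contain every term's genes.
    """

    def __init__(self, terms: Sequence[Term], background: GeneSet | None = None):
        seen: set[str] = set()
        for t in terms:
            if t.category not in CATEGORIES:
                raise ValueError(f"unknown category {t.category!r} for {t.term_id}")
            if t.term_id in seen:
                raise ValueError(f"duplicate term_id {t.term_id!r}")
            seen.add(t.term_id)
        self.terms = list(terms)
        if background is None:
            universe: set[str] = set()
            for t in terms:
                universe |= t.genes
            self.background = GeneSet("background", frozenset(universe))
        else:
            for t in terms:
                extra = t.genes - background.genes
                if extra:
                    raise ValueError(
                        f"term {t.term_id} has genes outside background: {sorted(extra)[:3]}"
                    )
            self.background = background
        if not self.background.genes:
            raise ValueError("annotation background is empty")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    k: int  # overlap with the query
    K: int  # term size
    n: int  # effective query size
    N: int  # background size
    p_value: float
    genes: frozenset[str]
    p_adjusted: float | None = None


def ora(
    query: GeneSet,
    db: AnnotationDB,
    alpha: float = 0.01,
    adjust: bool = False,
) -> tuple[list[EnrichmentRow], dict]:
    """Over-representation of a query set against every term of the database.

    Query genes absent from the background are excluded from n (and counted
    in the run report); terms with zero overlap are never reported.  Rows
    with p < alpha are returned sorted by p ascending.  With ``adjust``,
    Benjamini-Hochberg q-values are computed over all overlapping terms and
    the screen is applied to the q-value instead.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    effective = query.genes & db.background.genes
    dropped = len(query.genes) - len(effective)
    n, N = len(effective), len(db.background)
    scored: list[EnrichmentRow] = []
    for t in db.terms:
        overlap = t.genes & effective
        k, K = len(overlap), len(t.genes)
        if k == 0 or K == 0:
            continue
        if K > N:
            raise ValueError(f"term {t.term_id} larger than background")
        # upper tail P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        scored.append(
            EnrichmentRow(t.term_id, t.term_name, t.category, k, K, n, N, p, frozenset(overlap))
        )
    if adjust and scored:
        qvals = false_discovery_control([r.p_value for r in scored], method="bh")
        scored = [
            EnrichmentRow(r.term_id, r.term_name, r.category, r.k, r.K, r.n, r.N,
                          r.p_value, r.genes, float(q))
            for r, q in zip(scored, qvals)
        ]
        kept = [r for r in scored if r.p_adjusted < alpha]
    else:
        kept = [r for r in scored if r.p_value < alpha]
    kept.sort(key=lambda r: (r.p_value, r.term_id))
    report = {
        "query_size": len(query.genes),
        "effective_query_size": n,
        "dropped_outside_background": dropped,
        "background_size": N,
        "terms_tested": len(db.terms),
        "terms_overlapping": len(scored),
        "terms_significant": len(kept),
        "alpha": alpha,
        "adjusted": adjust,
    }
    return kept, report


def select_top(rows: Iterable[EnrichmentRow], k: int = 20) -> dict[str, list[EnrichmentRow]]:
    """Per-category top-k rows by enriched gene count (descending).

    Ties break by smaller p, then term_id.  Categories with fewer than k
    rows return everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[EnrichmentRow]] = {}
    rows = list(rows)
    for cat in CATEGORIES:
        cat_rows = [r for r in rows if r.category == cat]
        cat_rows.sort(key=lambda r: (-r.k, r.p_value, r.term_id))
        if cat_rows:
            out[cat] = cat_rows[:k]
    return out


def bubble_export(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Plot-ready table: name, category, overlap, gene ratio k/n, p-value."""
    records = [
        {
            "term_name": r.term_name,
            "category": r.category,
            "count": r.k,
            "gene_ratio": r.k / r.n if r.n else float("nan"),
            "p_value": r.p_value,
        }
        for r in rows
    ]
    return pd.DataFrame(records, columns=["term_name", "category", "count", "gene_ratio", "p_value"])


def rows_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    records = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "category": r.category,
            "overlap": r.k,
            "term_size": r.K,
            "query_size": r.n,
            "background_size": r.N,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "genes": ",".join(sorted(r.genes)),
        }
        for r in rows
    ]
    cols = ["term_id", "term_name", "category", "overlap", "term_size", "query_size",
            "background_size", "p_value", "p_adjusted", "genes"]
    return pd.DataFrame(records, columns=cols)


# ---------------------------------------------------------------------------
# GMT-style I/O: term_id <TAB> term_name|category <TAB> gene1 <TAB> gene2 ...


def read_gmt(path, background: GeneSet | None = None) -> AnnotationDB:
    terms: list[Term] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 tab-separated fields")
            term_id, descriptor = parts[0], parts[1]
            if "|" in descriptor:
                term_name, category = descriptor.rsplit("|", 1)
            else:
                term_name, category = descriptor, "KEGG"
            genes = frozenset(canonical_gene(g) for g in parts[2:] if g.strip())
            terms.append(Term(term_id, term_name, category, genes))
    return AnnotationDB(terms, background=background)


def write_gmt(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for t in db.terms:
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.term_name}|{t.category}\t{genes}\n")
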