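"""Typed graphs and the topological screens of the pipeline.

Three undirected simple graphs are built along the analysis: the bipartite
compound-target network, the PPI network (STRING-style combined-score edge
list filtered at >= 0.9 with isolated "free" genes removed), and the
compound-target-pathway network.  Main ingredients are compounds whose
degree AND betweenness centrality both exceed the mean over compound nodes;
hub genes are the top-k PPI nodes by degree.

Betweenness is Brandes' algorithm over unweighted shortest paths (networkx),
normalized by 2/((n-1)(n-2)) with n the whole-graph node count — the
convention Cytoscape applies to undirected graphs, including on disconnected
graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .target_assembly import GeneSet, canonical_gene

ROLES = ("compound", "target", "pathway")

__all__ = [
    "TypedGraph",
    "NetworkSummary",
    "build_compound_target_network",
    "centrality",
    "screen_main_ingredients",
    "build_ppi_network",
    "hub_genes",
    "build_ctp_network",
    "summarize",
    "read_ppi_edges",
    "write_graphml",
    "write_sif",
]


class TypedGraph:
    """Undirected simple graph whose nodes carry a role tag.

    Thin wrapper over :class:`networkx.Graph` enforcing role validity,
    no self-loops and (for compound-target graphs) bipartiteness.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()

    def add_node(self, node_id: str, role: str) -> None:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for node {node_id!r}")
        existing = self.g.nodes.get(node_id)
        if existing is not None and existing["role"] != role:
            raise ValueError(f"node {node_id!r} already has role {existing['role']!r}")
        self.g.add_node(node_id, role=role)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a!r}")
        if a not in self.g or b not in self.g:
            raise ValueError(f"edge endpoints must be added first: ({a!r}, {b!r})")
        self.g.add_edge(a, b)

    def nodes(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.g.nodes)
        return [n for n, r in self.g.nodes(data="role") if r == role]

    def role(self, node_id: str) -> str:
        return self.g.nodes[node_id]["role"]

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def degree(self, node_id: str) -> int:
        return self.g.degree(node_id)

    def assert_bipartite(self, role_a: str = "compound", role_b: str = "target") -> None:
        for a, b in self.g.edges:
            ra, rb = self.role(a), self.role(b)
            if {ra, rb} != {role_a, role_b}:
                raise ValueError(
                    f"edge ({a!r}, {b!r}) violates {role_a}-{role_b} bipartiteness"
                )


@dataclass
class NetworkSummary:
    """Node/edge counts and mean degrees of a constructed network."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    role_counts: dict = field(default_factory=dict)
    role_mean_degree: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "role_counts": self.role_counts,
            "role_mean_degree": self.role_mean_degree,
        }


def build_compound_target_network(
    per_compound: Mapping[str, GeneSet], therapeutic: GeneSet
) -> TypedGraph:
    """Bipartite compound-target graph restricted to the therapeutic set.

    Compounds with no surviving link and targets with no edge are omitted,
    so every node in the result has degree >= 1.
    """
    tg = TypedGraph()
    for compound, gene_set in sorted(per_compound.items()):
        genes = sorted(gene_set.genes & therapeutic.genes)
        if not genes:
            continue
        tg.add_node(compound, "compound")
        for gene in genes:
            tg.add_node(gene, "target")
            tg.add_edge(compound, gene)
    return tg


def centrality(graph: TypedGraph) -> pd.DataFrame:
    """Degree and normalized betweenness per node.

    Betweenness uses Brandes' algorithm with endpoints excluded and the
    2/((n-1)(n-2)) normalization; for graphs with fewer than 3 nodes every
    betweenness is 0.
    """
    g = graph.g
    if g.number_of_nodes() < 3:
        btw = {n: 0.0 for n in g.nodes}
    else:
        btw = nx.betweenness_centrality(g, normalized=True)
    rows = [
        {
            "node": n,
            "role": g.nodes[n]["role"],
            "degree": g.degree(n),
            "betweenness": btw[n],
        }
        for n in g.nodes
    ]
    return pd.DataFrame(rows, columns=["node", "role", "degree", "betweenness"])


def screen_main_ingredients(
    graph: TypedGraph, strict: bool = True
) -> tuple[set[str], float, float]:
    """Compounds exceeding the compound-node means of degree and betweenness.

    Means are computed over compound nodes only; both inequalities are strict
    by default ("greater than the mean"), configurable to >=.
    """
    table = centrality(graph)
    compounds = table[table["role"] == "compound"]
    if compounds.empty:
        raise ValueError("graph has no compound nodes")
    mean_deg = float(compounds["degree"].mean())
    mean_btw = float(compounds["betweenness"].mean())
    if strict:
        mask = (compounds["degree"] > mean_deg) & (compounds["betweenness"] > mean_btw)
    else:
        mask = (compounds["degree"] >= mean_deg) & (compounds["betweenness"] >= mean_btw)
    return set(compounds.loc[mask, "node"]), mean_deg, mean_btw


def build_ppi_network(
    edges: pd.DataFrame, genes: GeneSet, threshold: float = 0.9
) -> TypedGraph:
    """PPI graph from a combined-score edge list.

    Keeps edges with combined_score >= threshold between genes of the
    therapeutic set; genes left without any retained edge ("free" genes)
    are not added as nodes.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    required = {"gene_a", "gene_b", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"PPI table missing columns: {sorted(missing)}")
    scores = pd.to_numeric(edges["combined_score"], errors="coerce")
    bad = edges.index[scores.isna() | (scores < 0) | (scores > 1)]
    if len(bad):
        raise ValueError(f"malformed combined_score in PPI rows {list(bad[:5])}")
    tg = TypedGraph()
    for idx, row in edges.iterrows():
        a, b = canonical_gene(row["gene_a"]), canonical_gene(row["gene_b"])
        if a == b:
            raise ValueError(f"self-interaction rejected at PPI row {idx}")
        if scores[idx] < threshold:
            continue
        if a not in genes or b not in genes:
            continue
        tg.add_node(a, "target")
        tg.add_node(b, "target")
        tg.add_edge(a, b)
    return tg


def hub_genes(
    graph: TypedGraph, k: int = 10
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Top-k nodes by degree (ties alphabetical), plus any overflow ties.

    If nodes beyond position k share the k-th degree they are returned in a
    companion overflow list rather than silently dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        ((n, graph.degree(n)) for n in graph.nodes()), key=lambda t: (-t[1], t[0])
    )
    top = ranked[:k]
    overflow: list[tuple[str, int]] = []
    if len(ranked) > k:
        cut_degree = top[-1][1]
        overflow = [t for t in ranked[k:] if t[1] == cut_degree]
    return top, overflow


def build_ctp_network(
    graph: TypedGraph,
    pathway_membership: Mapping[str, GeneSet],
    top_pathways: Sequence[str],
) -> TypedGraph:
    """Compound-target-pathway network.

    Nodes are the selected pathways, the compound-target-graph targets that
    belong to at least one selected pathway, and the compounds that retain
    at least one edge to such a target.  Edges are the restricted
    compound-target links plus target-pathway membership links.
    """
    missing = [p for p in top_pathways if p not in pathway_membership]
    if missing:
        raise ValueError(f"pathways not in membership map: {missing}")
    graph.assert_bipartite()
    network_targets = set(graph.nodes("target"))
    retained: set[str] = set()
    for p in top_pathways:
        retained |= pathway_membership[p].genes & network_targets
    tg = TypedGraph()
    for compound in graph.nodes("compound"):
        kept = [t for t in graph.g.neighbors(compound) if t in retained]
        if not kept:
            continue
        tg.add_node(compound, "compound")
        for t in kept:
            tg.add_node(t, "target")
            tg.add_edge(compound, t)
    for p in top_pathways:
        members = pathway_membership[p].genes & retained
        if not members:
            continue
        tg.add_node(p, "pathway")
        for t in sorted(members):
            tg.add_node(t, "target")
            tg.add_edge(t, p)
    return tg


def summarize(graph: TypedGraph) -> NetworkSummary:
    """Whole-graph and per-role node counts and mean degrees."""
    n, e = graph.n_nodes, graph.n_edges
    role_counts: dict[str, int] = {}
    role_mean: dict[str, float] = {}
    for role in ROLES:
        nodes = graph.nodes(role)
        if not nodes:
            continue
        role_counts[role] = len(nodes)
        role_mean[role] = sum(graph.degree(x) for x in nodes) / len(nodes)
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        mean_degree=(2 * e / n) if n else 0.0,
        role_counts=role_counts,
        role_mean_degree=role_mean,
    )


# ---------------------------------------------------------------------------
# Tabular / graph I/O


def read_ppi_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def write_graphml(graph: TypedGraph, path) -> None:
    nx.write_graphml(graph.g, path)


def write_sif(graph: TypedGraph, path, relation: str = "interacts") -> None:
    """Simple interaction format: `nodeA relation nodeB`, one edge per line."""
    with open(path, "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), graph.g.edges)):
            fh.write(f"{a}\t{relation}\t{b}\n")
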