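"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the definition, sharing no code with the package
paths it validates: formula search by exhaustive grid enumeration,
betweenness by explicit all-pairs shortest-path counting, hypergeometric
tail probabilities by enumerating every possible query draw.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np

ORACLE_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
    "S": 31.97207100,
    "P": 30.97376163,
}


class GridFormulaEnumerator:
    """Full-grid formula search: every composition inside the bounds is
    materialized once, then filtered by adduct m/z tolerance per query.

    Only practical for small bounds; returns frozen (element, count) tuples
    of non-empty compositions, with no RDBE filtering.
    """

    def __init__(self, bounds: dict[str, tuple[int, int]]):
        self.elements = sorted(bounds)
        ranges = [np.arange(bounds[e][0], bounds[e][1] + 1) for e in self.elements]
        grids = np.meshgrid(*ranges, indexing="ij")
        self.counts = np.stack([g.ravel() for g in grids], axis=1)
        self.masses = self.counts @ np.array(
            [ORACLE_MASSES[e] for e in self.elements])

    def __call__(self, observed_mz: float, adduct_delta: float,
                 tolerance_ppm: float) -> set[tuple[tuple[str, int], ...]]:
        theo = self.masses + adduct_delta
        with np.errstate(divide="ignore", invalid="ignore"):
            ppm = np.abs(observed_mz - theo) / theo * 1e6
        ok = (theo > 0) & (ppm <= tolerance_ppm) & (self.counts.sum(axis=1) > 0)
        out = set()
        for row in self.counts[ok]:
            out.add(tuple((e, int(c))
                          for e, c in zip(self.elements, row) if c))
        return out


def brute_force_formulas(observed_mz, adduct_delta, bounds, tolerance_ppm):
    return GridFormulaEnumerator(bounds)(observed_mz, adduct_delta, tolerance_ppm)


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Normalized betweenness by enumerating every shortest path explicitly."""
    n = g.number_of_nodes()
    score = {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = 2.0 / ((n - 1) * (n - 2))
    return {v: score[v] * norm for v in nodes}


def exact_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) equally likely query draws."""
    term = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    assert total == comb(N, n)
    return hits / total
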