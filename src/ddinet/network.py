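"""Coexpression-weighted PPI graph and target-distance baselines.

Each PPI edge is weighted by the Pearson correlation coefficient (PCC) of
its two genes' expression profiles across tissues.  The mean and sample SD
of all defined edge weights serve as the network-wide background against
which the S-score measures connection strength.  Edges whose genes lack
expression data (or have a zero-variance profile) stay in the graph for
topology purposes -- distances and neighborhoods -- but carry no weight and
are excluded from the background statistics.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedNetwork",
    "weight_edges",
    "background_stats",
    "min_target_distance",
    "target_overlap",
]


class WeightedNetwork:
    """Undirected gene graph with optional per-edge PCC weights.

    Edge weights live in the ``weight`` attribute of the underlying
    :class:`networkx.Graph`; an edge without that attribute has an
    undefined weight.  Background mean/SD over the defined weights are
    computed on construction and cached.
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges()):
            raise ValueError("self-loops are not allowed")
        self.graph = graph
        self._refresh_background()

    def _refresh_background(self) -> None:
        weights = self.defined_weights()
        if len(weights) >= 2:
            self._mu_bg = float(np.mean(weights))
            self._sigma_bg = float(np.std(weights, ddof=1))
        elif len(weights) == 1:
            self._mu_bg = float(weights[0])
            self._sigma_bg = None
        else:
            self._mu_bg = None
            self._sigma_bg = None

    def defined_weights(self) -> np.ndarray:
        return np.array([w for _, _, w in
                         self.graph.edges(data="weight") if w is not None],
                        dtype=float)

    @property
    def background_mean(self) -> float | None:
        return self._mu_bg

    @property
    def background_sd(self) -> float | None:
        return self._sigma_bg

    def weight(self, u: str, v: str) -> float | None:
        """Weight of edge (u, v), or None if the edge is unweighted."""
        return self.graph.edges[u, v].get("weight")

    def add_edge(self, u: str, v: str, weight: float | None = None) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if weight is None:
            self.graph.add_edge(u, v)
        else:
            self.graph.add_edge(u, v, weight=float(weight))
        self._refresh_background()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()


def weight_edges(edges: pd.DataFrame, expr: pd.DataFrame) -> WeightedNetwork:
    """Build a :class:`WeightedNetwork` from an edge table and expression.

    Every edge whose two genes both have expression rows gets the Pearson
    correlation of their tissue vectors as weight; other edges remain
    unweighted.  Genes with a zero-variance profile yield undefined
    weights on all their edges (a PCC against a constant vector does not
    exist) and are logged.
    """
    graph = nx.Graph()
    mat = expr.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(expr.index)}
    n = mat.shape[1]
    sd = mat.std(axis=1, ddof=1)
    zero_var = set(expr.index[sd == 0.0])
    if zero_var:
        logger.warning("%d gene(s) with zero-variance expression; their "
                       "edges get undefined weights", len(zero_var))
    # standardized rows: PCC(a, b) = dot(z_a, z_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mat - mat.mean(axis=1, keepdims=True)) / (
            sd[:, None] * math.sqrt(n - 1))
    for row in edges.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        ia, ib = index.get(a), index.get(b)
        if (ia is None or ib is None or a in zero_var or b in zero_var):
            graph.add_edge(a, b)
            continue
        w = float(np.clip(np.dot(z[ia], z[ib]), -1.0, 1.0))
        graph.add_edge(a, b, weight=w)
    return WeightedNetwork(graph)


def background_stats(net: WeightedNetwork) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator) of all defined edge weights."""
    weights = net.defined_weights()
    if len(weights) < 2:
        raise ValueError("background statistics need >= 2 weighted edges, "
                         f"got {len(weights)}")
    return float(np.mean(weights)), float(np.std(weights, ddof=1))


def _multi_source_bfs(graph: nx.Graph, sources: Iterable[str]) -> dict[str, int]:
    """Hop distances from the nearest source to every reachable node."""
    dist: dict[str, int] = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        for v in graph.adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def min_target_distance(targets_a: Iterable[str], targets_b: Iterable[str],
                        net: WeightedNetwork) -> int | None:
    """Minimum shortest-path hop count between two drugs' target sets.

    Zero iff the sets share a gene present in the network; ``None`` if
    either drug has no in-network target or the sets lie in disconnected
    components.  Distances are unweighted hop counts (Dijkstra with unit
    weights reduces to BFS).
    """
    in_a = {t for t in targets_a if t in net.graph}
    in_b = {t for t in targets_b if t in net.graph}
    if not in_a or not in_b:
        return None
    if in_a & in_b:
        return 0
    if len(in_b) < len(in_a):
        in_a, in_b = in_b, in_a
    dist = _multi_source_bfs(net.graph, in_a)
    best = min((dist[t] for t in in_b if t in dist), default=None)
    return best


def target_overlap(targets_a: Iterable[str], targets_b: Iterable[str]) -> bool:
    """True iff the two drugs share at least one target protein.

    Network membership is not required -- this is the pure target-overlap
    baseline.
    """
    return bool(set(targets_a) & set(targets_b))
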