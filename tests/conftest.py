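"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the code paths they check: naive
covariance-formula PCC, exhaustive edge enumeration for connection
profiles, direct one-sample t arithmetic, and brute-force Mann-Whitney
concordance counting for AUC.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from ddinet.pipeline import score_pairs
from ddinet.simulate import default_config, generate_benchmark


# ---------------------------------------------------------------- oracles

def naive_pcc(x, y) -> float:
    """Pearson correlation by the plain covariance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    return cov / (sx / 1) / sy


def naive_mean_sd(values) -> tuple[float, float]:
    """Sample mean and SD with the n-1 denominator, by direct formula."""
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def brute_force_profile(genes_a: set, genes_b: set,
                        graph: nx.Graph) -> list[float]:
    """All connecting-edge PCCs + one 1.0 per shared gene, by full scan."""
    pccs = []
    for u, v, w in graph.edges(data="weight"):
        crosses = ((u in genes_a and v in genes_b)
                   or (u in genes_b and v in genes_a))
        if crosses and w is not None:
            pccs.append(w)
    pccs.extend(1.0 for _ in genes_a & genes_b)
    return pccs


def brute_force_s(pccs: list[float], mu_bg: float,
                  sigma_bg: float) -> float | None:
    """S statistic by direct arithmetic on the PCC list."""
    n = len(pccs)
    if n == 0:
        return None
    mean, sd = naive_mean_sd(pccs)
    if sd == 0.0:
        sd = sigma_bg
    if sd == 0.0:
        return None
    return (mean - mu_bg) / (sd / math.sqrt(n))


def brute_force_auc(scores: list[float | None],
                    labels: list[int]) -> float:
    """Mann-Whitney concordance with ties = 1/2; undefined ranks last."""
    defined = [s for s in scores if s is not None]
    floor = (min(defined) - 1.0) if defined else 0.0
    vals = [floor if s is None else s for s in scores]
    pos = [v for v, y in zip(vals, labels) if y == 1]
    neg = [v for v, y in zip(vals, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_min_distance(targets_a, targets_b,
                             graph: nx.Graph) -> int | None:
    """Minimum pairwise hop distance via per-pair single-source BFS."""
    best = None
    for ta in targets_a:
        if ta not in graph:
            continue
        lengths = nx.single_source_shortest_path_length(graph, ta)
        for tb in targets_b:
            if tb in lengths and (best is None or lengths[tb] < best):
                best = lengths[tb]
    return best


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def default_benchmark():
    """Default synthetic benchmark (seed 1), generated once per session."""
    return generate_benchmark(default_config(seed=1))


@pytest.fixture(scope="session")
def default_records(default_benchmark):
    """Scored pairs of the default benchmark."""
    edges, expr, targets, se, ddis, truth = default_benchmark
    return score_pairs(edges, expr, targets, side_effects=se)


@pytest.fixture
def tiny_expr_file(tmp_path):
    """A well-formed 3-gene x 4-tissue expression TSV."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tliver\tbrain\theart\tlung\n"
        "A\t1\t2\t3\t4\n"
        "B\t2\t4\t6\t8\n"
        "C\t4\t3\t2\t1\n")
    return path


def random_weighted_graph(rng: np.random.Generator, n_nodes: int,
                          p: float) -> nx.Graph:
    """Random graph with PCC-like weights; some edges left unweighted."""
    nodes = [f"g{i}" for i in range(n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for u, v in combinations(nodes, 2):
        if rng.random() < p:
            if rng.random() < 0.1:
                graph.add_edge(u, v)  # undefined weight
            else:
                graph.add_edge(u, v,
                               weight=float(rng.uniform(-1.0, 1.0)))
    return graph
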