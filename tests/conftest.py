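"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each statistic from its definition by explicit
enumeration (combinatorial sums, triple loops, path enumeration) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest

from imcc import (
    ModulePartition,
    ScreeningConfig,
    WeightedNetwork,
    default_design,
    make_modular_network,
    score_condition,
)

# ---------------------------------------------------------------------------
# oracles


def hypergeom_tail_oracle(x: int, n: int, M: int, N: int) -> float:
    """P[K >= x] by direct combinatorial summation (exact for small N)."""
    total = comb(N, n)
    s = 0
    for k in range(x, n + 1):
        if k > M or n - k > N - M:
            continue
        s += comb(M, k) * comb(N - M, n - k)
    return s / total


def path_strength_oracle(net: WeightedNetwork, part: ModulePartition, pair) -> float:
    """Triple loop over all outset-mediator-end paths."""
    a, b = sorted(map(str, pair))
    mx, my = set(part.members(a)), set(part.members(b))
    total = 0.0
    for m in net.graph.nodes:
        if m in mx or m in my:
            continue
        w_m = sum(d["weight"] for d in net.graph[m].values())
        for o in net.graph[m]:
            if o not in mx:
                continue
            for e in net.graph[m]:
                if e not in my:
                    continue
                total += (net.graph[m][o]["weight"] / w_m) * (
                    net.graph[m][e]["weight"] / w_m
                )
    return total


def consistency_oracle(net: WeightedNetwork, part: ModulePartition, pair) -> float:
    """Per-gene term-by-term evaluation of the consistency score."""
    a, b = sorted(map(str, pair))
    mx, my = set(part.members(a)), set(part.members(b))
    c_total = net.graph.number_of_nodes()
    s, t = len(mx), len(my)
    total = 0.0
    for i in net.graph.nodes:
        if i in mx or i in my:
            continue
        cl = net.graph.degree(i)
        if cl == 0:
            continue
        cm_x = sum(1 for v in net.graph[i] if v in mx)
        cm_y = sum(1 for v in net.graph[i] if v in my)
        w_i = sum(d["weight"] for d in net.graph[i].values())
        term = min(cm_x - (s / c_total) * cl, cm_y - (t / c_total) * cl)
        term *= (cm_x * cm_y) / cl
        term *= w_i
        if cm_x and cm_y:
            total += term
    return total


def bfs_distances(g: nx.Graph, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(g: nx.Graph, s, t, cutoff: int):
    """Enumerate shortest s-t paths by depth-first search with distance
    pruning; returns the list of node tuples."""
    dist_t = bfs_distances(g, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(u, path):
        if u == t:
            paths.append(tuple(path))
            return
        for v in g[u]:
            if v not in path and v in dist_t and len(path) + dist_t[v] <= cutoff:
                path.append(v)
                walk(v, path)
                path.pop()

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist_t[s]]


def betweenness_oracle(g: nx.Graph) -> dict:
    """Normalized node betweenness by explicit shortest-path enumeration."""
    nodes = list(g.nodes)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t, cutoff=n)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            bc[v] += frac
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: b * scale for v, b in bc.items()}
    return bc


def cpl_oracle(g: nx.Graph) -> float:
    lengths = []
    for s, t in combinations(list(g.nodes), 2):
        dist = bfs_distances(g, s)
        if t in dist:
            lengths.append(dist[t])
    return float(np.mean(lengths)) if lengths else float("nan")


def chi_square_oracle(obs: np.ndarray) -> float:
    """Textbook sum of (O-E)^2/E for a contingency table."""
    obs = np.asarray(obs, dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def random_gene_network(seed: int, n_nodes: int = 18, p_edge: float = 0.25):
    """Random weighted network + 3-module partition for oracle comparisons."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(genes[i], genes[j], weight=float(rng.uniform(0.05, 1.0)))
    labels = ["blue", "brown", "grey"]
    assignment = {g_: labels[i % 3] for i, g_ in enumerate(genes)}
    return WeightedNetwork(g, weight_floor=0.0), ModulePartition(assignment)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def planted_condition():
    """The standard 374-gene recovery design, generated once per session."""
    design = default_design(seed=11)
    net, part, truth = make_modular_network(design)
    return design, net, part, truth


@pytest.fixture(scope="session")
def planted_scores(planted_condition):
    _, net, part, _ = planted_condition
    return score_condition(net, part, ScreeningConfig())


@pytest.fixture()
def toy_two_modules():
    """Two singleton modules joined by one edge of weight 0.5."""
    net = WeightedNetwork.from_edges([("a", "b", 0.5)], weight_floor=0.0)
    part = ModulePartition({"a": "x", "b": "y"})
    return net, part
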