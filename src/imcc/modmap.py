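"""Module-level map construction and global rewiring statistics.

The modular map abstracts a condition into a weighted graph whose nodes are
modules and whose edge weights are the final coordination scores.  Rewiring
across conditions is quantified four ways:

* a table of topological parameters (degree, density, characteristic path
  length, diameter, betweenness, clustering, Freeman degree centralization,
  mean edge weight);
* a shift test on the score distribution: scores are −log2-transformed,
  binned into four intervals (reference-condition quartiles by default) and
  compared by a 2×4 chi-square contingency test;
* PCA of the per-condition relative bin frequencies;
* Euclidean distance between condition architectures in the min-max
  normalized (avg_weight, density, centrality) space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .netio import ModulePartition

__all__ = [
    "ModularMap",
    "TopoSummary",
    "DistributionProfile",
    "build_map",
    "topo_summary",
    "percent_change",
    "quartile_edges",
    "bin_distribution",
    "rewiring_test",
    "pca_profiles",
    "architecture_distance",
]


@dataclass
class ModularMap:
    """Simple undirected module graph; edge weight = final IMCC (> 0)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if w is None or w <= 0:
                raise ValueError(f"modular-map edge {u!r}-{v!r} needs weight > 0, got {w}")

    @property
    def modules(self) -> list:
        return sorted(self.graph.nodes, key=str)

    @property
    def n_modules(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_weights(self) -> list[float]:
        return [w for _, _, w in self.graph.edges(data="weight")]


#: Column order mirrors the per-condition topology table.
TOPO_FIELDS = [
    "avg_degree",
    "density",
    "characteristic_path_length",
    "diameter",
    "avg_betweenness",
    "cluster_coefficient",
    "centrality",
    "avg_weight",
]


@dataclass
class TopoSummary:
    avg_degree: float
    density: float
    characteristic_path_length: float
    diameter: float
    avg_betweenness: float
    cluster_coefficient: float
    centrality: float
    avg_weight: float

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in TOPO_FIELDS}


@dataclass
class DistributionProfile:
    """Counts of −log2(score) values in four right-closed intervals."""

    bin_edges: tuple  # (e1, e2, e3): (−inf,e1] (e1,e2] (e2,e3] (e3,+inf)
    counts: np.ndarray  # 4 ints
    relative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.size != 4 or (self.counts < 0).any():
            raise ValueError("profile needs 4 non-negative counts")
        total = self.counts.sum()
        if total == 0:
            raise ValueError("profile needs at least one scored pair")
        self.relative = self.counts / total


def build_map(table: pd.DataFrame, part: ModulePartition) -> ModularMap:
    """One node per module, one edge per pair carrying a positive final IMCC."""
    g = nx.Graph()
    g.add_nodes_from(part.module_labels)
    if not table.empty and "imcc" in table:
        for a, b, w in zip(table["module_a"], table["module_b"], table["imcc"]):
            if np.isfinite(w) and w > 0:
                g.add_edge(str(a), str(b), weight=float(w))
    return ModularMap(g)


# ---------------------------------------------------------------------------
# topology


def _connected_pair_paths(g: nx.Graph) -> list[int]:
    """Unweighted shortest-path lengths over all connected unordered pairs."""
    lengths = []
    nodes = sorted(g.nodes, key=str)
    order = {n: i for i, n in enumerate(nodes)}
    for u in nodes:
        dist = nx.single_source_shortest_path_length(g, u)
        for v, d in dist.items():
            if order[v] > order[u]:
                lengths.append(d)
    return lengths


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over connected pairs (NaN if none)."""
    lengths = _connected_pair_paths(g)
    return float(np.mean(lengths)) if lengths else float("nan")


def degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization: sum(k_max − k_i) / ((n−1)(n−2))."""
    n = g.number_of_nodes()
    if n < 3:
        return float("nan")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def topo_summary(mmap: ModularMap) -> TopoSummary:
    """The eight Table-style topological parameters of a modular map."""
    g = mmap.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("modular map is empty")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    lengths = _connected_pair_paths(g)
    bc = nx.betweenness_centrality(g, normalized=True)
    weights = mmap.edge_weights
    return TopoSummary(
        avg_degree=float(degrees.mean()),
        density=float(nx.density(g)),
        characteristic_path_length=float(np.mean(lengths)) if lengths else float("nan"),
        diameter=float(max(lengths)) if lengths else float("nan"),
        avg_betweenness=float(np.mean(list(bc.values()))),
        cluster_coefficient=float(nx.average_clustering(g)) if n else float("nan"),
        centrality=degree_centralization(g),
        avg_weight=float(np.mean(weights)) if weights else float("nan"),
    )


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100·(after − before)/before, one decimal."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return round(100.0 * (after - before) / before, 1)


# ---------------------------------------------------------------------------
# score-distribution shift


def quartile_edges(values) -> tuple:
    """Quartiles of −log2(values): default interval edges from a reference
    condition's scores."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError("scores must be positive for the −log2 transform")
    t = -np.log2(v)
    q1, q2, q3 = np.quantile(t, [0.25, 0.5, 0.75])
    return (float(q1), float(q2), float(q3))


def bin_distribution(values, edges) -> DistributionProfile:
    """Count −log2(values) into (−inf,e1], (e1,e2], (e2,e3], (e3,+inf).

    Intervals are right-closed: a value landing exactly on an edge goes to
    the lower bin.
    """
    e1, e2, e3 = edges
    if not (e1 <= e2 <= e3):
        raise ValueError(f"edges must be non-decreasing, got {edges}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no scores to bin")
    if (v <= 0).any():
        raise ValueError("scores must be positive for the −log2 transform")
    t = -np.log2(v)
    idx = np.searchsorted([e1, e2, e3], t, side="left")
    counts = np.bincount(idx, minlength=4)
    return DistributionProfile(bin_edges=(float(e1), float(e2), float(e3)), counts=counts)


def rewiring_test(profile_a: DistributionProfile, profile_b: DistributionProfile):
    """Chi-square contingency test on two binned score distributions.

    2×4 test without continuity correction; columns whose expected count
    under independence falls below 1 are merged with the nearest neighbor
    (warned).  Returns ``(statistic, p_value)``; identical or proportional
    profiles give statistic 0, p = 1.
    """
    if profile_a.bin_edges != profile_b.bin_edges:
        raise ValueError("profiles were binned with different edges")
    obs = np.vstack([profile_a.counts, profile_b.counts]).astype(float)

    def expected(o):
        return np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()

    while obs.shape[1] > 2 and (expected(obs) < 1).any():
        col = int(np.argmin(expected(obs).min(axis=0)))
        neighbor = col - 1 if col > 0 else col + 1
        lo, hi = sorted((col, neighbor))
        merged = obs[:, lo] + obs[:, hi]
        obs = np.delete(obs, hi, axis=1)
        obs[:, lo] = merged
        warnings.warn("merged a low-expectation bin for the chi-square test", stacklevel=2)
    if np.allclose(obs[0] / obs[0].sum(), obs[1] / obs[1].sum()):
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def pca_profiles(profiles: dict) -> pd.DataFrame:
    """First two principal-component scores of per-condition bin frequencies.

    ``profiles`` maps condition label → DistributionProfile (or 4-vector of
    relative frequencies).  Columns are centered, not scaled; the sign of each
    component is fixed so its largest-|loading| element is positive.
    """
    labels = list(profiles)
    rows = []
    for lab in labels:
        p = profiles[lab]
        rows.append(p.relative if isinstance(p, DistributionProfile) else np.asarray(p, float))
    x = np.vstack(rows)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(2, vt.shape[0])
    scores = np.zeros((len(labels), 2))
    for c in range(k):
        load = vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
            u[:, c] = -u[:, c]
        scores[:, c] = u[:, c] * s[c]
    return pd.DataFrame(scores, index=labels, columns=["pc1", "pc2"])


def architecture_distance(summaries: dict, reference: str) -> pd.Series:
    """Per-condition Euclidean distance to the reference architecture.

    The three representative indexes (avg_weight, density, centrality) are
    min-max normalized across conditions; each condition's distance to the
    reference is taken in that normalized 3-space.
    """
    if reference not in summaries:
        raise KeyError(f"reference condition {reference!r} not among summaries")
    labels = list(summaries)
    mat = np.array(
        [
            [summaries[c].avg_weight, summaries[c].density, summaries[c].centrality]
            for c in labels
        ],
        dtype=float,
    )
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (mat - lo) / span
    ref = norm[labels.index(reference)]
    dist = np.sqrt(((norm - ref) ** 2).sum(axis=1))
    return pd.Series(dist, index=labels, name="architecture_distance")
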