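"""Containers and tabular I/O for expression data, weighted networks,
module partitions and module annotations.

All on-disk formats are plain TSV:

* expression — header row of sample ids, first column gene ids;
* edge list — ``gene_a  gene_b  weight`` with weight in (0, 1], ``#`` comments;
* partition — ``gene  module``;
* annotations — ``module  category`` (one row per category).

The weighted network is an unsigned co-expression adjacency: edge weight
``a_ij = |cor(x_i, x_j)|**power`` with entries below a floor (default 0.02)
dropped.  Genes whose every adjacency entry falls below the floor stay in the
network as isolated nodes — several downstream statistics sum over *all*
genes, not just connected ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "WeightedNetwork",
    "ModulePartition",
    "UNASSIGNED",
    "read_expression",
    "build_adjacency",
    "pick_soft_power",
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
    "read_annotations",
    "write_annotations",
    "write_graphml",
]

#: Reserved module label excluded from all pair scoring.
UNASSIGNED = "unassigned"

DEFAULT_WEIGHT_FLOOR = 0.02


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (arbitrary units, no missing data)."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if self.data.shape[1] < 3:
            raise ValueError(
                f"at least 3 samples required for correlation, got {self.data.shape[1]}"
            )
        if self.data.isna().any().any():
            raise ValueError("missing expression values are not accepted")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class WeightedNetwork:
    """Symmetric non-negative gene-gene adjacency above a weight floor.

    Thin wrapper around :class:`networkx.Graph`; isolated genes are kept as
    nodes so that whole-network gene counts and degree sums are well defined.
    """

    graph: nx.Graph
    weight_floor: float = DEFAULT_WEIGHT_FLOOR

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop on gene {u!r}")
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"weight out of range (0, 1] on edge {u!r}-{v!r}: {w}")
            if w < self.weight_floor:
                raise ValueError(
                    f"edge {u!r}-{v!r} weight {w} below floor {self.weight_floor}"
                )

    @classmethod
    def from_edges(
        cls,
        edges,
        nodes=(),
        weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    ) -> "WeightedNetwork":
        """Build from an iterable of ``(gene_a, gene_b, weight)`` triples."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w))
        return cls(g, weight_floor=weight_floor)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u, v) -> float:
        """Edge weight a_ij, 0 when the edge is absent."""
        d = self.graph.get_edge_data(u, v)
        return 0.0 if d is None else d["weight"]

    def degree(self, u) -> int:
        """Link count CL_i of a gene."""
        return self.graph.degree(u)

    def weighted_degree(self, u) -> float:
        """Sum of incident edge weights W_i of a gene."""
        return float(self.graph.degree(u, weight="weight"))

    def neighbors(self, u):
        return self.graph.neighbors(u)


@dataclass
class ModulePartition:
    """Disjoint assignment of genes to labeled modules.

    The reserved label ``"unassigned"`` may hold genes that belong to no
    module; it is excluded from :attr:`module_labels` and hence from all
    pair scoring.
    """

    assignment: dict = field(default_factory=dict)  # gene -> module label

    def __post_init__(self) -> None:
        for gene, label in self.assignment.items():
            if not str(label):
                raise ValueError(f"empty module label for gene {gene!r}")

    @property
    def module_labels(self) -> list[str]:
        labels = {m for m in self.assignment.values() if m != UNASSIGNED}
        return sorted(labels)

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def members(self, label: str) -> list:
        """Genes assigned to a module (sorted for determinism)."""
        genes = sorted(g for g, m in self.assignment.items() if m == label)
        if not genes and label != UNASSIGNED:
            raise KeyError(f"unknown or empty module label {label!r}")
        return genes

    def module_of(self, gene):
        return self.assignment.get(gene)

    def size(self, label: str) -> int:
        return len(self.members(label))


# ---------------------------------------------------------------------------
# expression


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# adjacency construction


def build_adjacency(
    expr: ExpressionMatrix,
    power: int,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> WeightedNetwork:
    """Soft-threshold adjacency a_ij = |pearson(x_i, x_j)|**power.

    Entries below ``weight_floor`` are dropped; every gene remains a node.
    Constant-expression genes have undefined correlation and are rejected.
    """
    if power < 1:
        raise ValueError(f"power must be >= 1, got {power}")
    if not (0.0 <= weight_floor < 1.0):
        raise ValueError(f"weight_floor must lie in [0, 1), got {weight_floor}")
    x = expr.values
    sd = x.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [expr.gene_ids[i] for i in constant]
        raise ValueError(f"constant expression (undefined correlation) for gene(s): {names}")
    corr = np.corrcoef(x)
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    genes = expr.gene_ids
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = a[iu, ju] >= weight_floor
    for i, j in zip(iu[keep], ju[keep]):
        # clip fp noise so |r|=1 pairs store exactly 1.0
        g.add_edge(genes[i], genes[j], weight=float(min(a[i, j], 1.0)))
    return WeightedNetwork(g, weight_floor=weight_floor)


def _scale_free_r2(expr: ExpressionMatrix, power: int, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution regression for one power.

    Connectivity k_i = sum_j a_ij (weighted, unthresholded); k values are cut
    into up to ``n_bins`` equal-count bins and log10(frequency) is regressed
    on log10(mean k) across bins.
    """
    corr = np.corrcoef(expr.values)
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    k = k[k > 0]
    if np.unique(np.round(k, 12)).size < 3:
        return float("nan")
    quantiles = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    if edges.size < 4:  # need >= 3 bins
        return float("nan")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    mean_k = np.array([k[idx == b].mean() for b in range(edges.size - 1) if (idx == b).any()])
    freq = np.array([(idx == b).sum() for b in range(edges.size - 1) if (idx == b).any()])
    freq = freq / freq.sum()
    lx, ly = np.log10(mean_k), np.log10(freq)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - (resid**2).sum() / ss_tot)


def pick_soft_power(
    expr: ExpressionMatrix,
    candidates=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_threshold: float = 0.8,
) -> int:
    """Smallest candidate power whose scale-free fit R^2 >= threshold.

    Falls back to the candidate with maximal R^2 when none reaches the
    threshold.  Raises if the fit is undefined for every candidate.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if len(candidates) == 1:
        return candidates[0]
    r2 = {p: _scale_free_r2(expr, p) for p in candidates}
    defined = {p: v for p, v in r2.items() if np.isfinite(v)}
    if not defined:
        raise ValueError("scale-free fit undefined for every candidate power")
    for p in sorted(defined):
        if defined[p] >= r2_threshold:
            return p
    return max(sorted(defined), key=lambda p: defined[p])


# ---------------------------------------------------------------------------
# edge list / partition / annotation tables


def read_network(path, weight_floor: float = 0.0) -> WeightedNetwork:
    """Read a TSV edge list (``gene_a  gene_b  weight``).

    ``weight_floor`` defaults to 0 on read: a stored file is trusted to have
    been thresholded by its producer.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene_a", "gene_b", "weight"]
    )
    if df.iloc[0]["gene_a"] == "gene_a":  # optional header row
        df = df.iloc[1:]
    g = nx.Graph()
    for row in df.itertuples(index=False):
        u, v, w = str(row.gene_a), str(row.gene_b), float(row.weight)
        if u == v:
            raise ValueError(f"self-loop on gene {u!r} in {path}")
        if not (0.0 < w <= 1.0):
            raise ValueError(f"weight out of range (0, 1]: {w} on {u}-{v} in {path}")
        if g.has_edge(u, v) and g[u][v]["weight"] != w:
            raise ValueError(f"conflicting duplicate edge {u}-{v} in {path}")
        g.add_edge(u, v, weight=w)
    return WeightedNetwork(g, weight_floor=weight_floor)


def write_network(net: WeightedNetwork, path) -> None:
    rows = sorted(
        (min(str(u), str(v)), max(str(u), str(v)), w)
        for u, v, w in net.graph.edges(data="weight")
    )
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_partition(path, net: WeightedNetwork | None = None) -> ModulePartition:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "module"])
    if str(df.iloc[0]["gene"]) == "gene":
        df = df.iloc[1:]
    assignment: dict = {}
    for row in df.itertuples(index=False):
        gene, module = str(row.gene), str(row.module)
        if module in ("", "nan"):
            raise ValueError(f"empty module label for gene {gene!r} in {path}")
        if gene in assignment:
            raise ValueError(f"gene {gene!r} assigned to more than one module in {path}")
        assignment[gene] = module
    part = ModulePartition(assignment)
    if net is not None:
        missing = sorted(set(assignment) - set(net.graph.nodes))
        if missing:
            warnings.warn(
                f"{len(missing)} partition gene(s) absent from the network "
                f"(treated as isolated): {missing[:5]}...",
                stacklevel=2,
            )
    return part


def write_partition(part: ModulePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for gene in sorted(part.assignment, key=str):
            fh.write(f"{gene}\t{part.assignment[gene]}\n")


def read_annotations(path) -> dict:
    """Read a ``module  category`` TSV into {module_label: set(categories)}."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["module", "category"])
    if str(df.iloc[0]["module"]) == "module":
        df = df.iloc[1:]
    out: dict = {}
    for row in df.itertuples(index=False):
        module, cat = str(row.module), str(row.category)
        if not module or module == "nan":
            raise ValueError(f"empty module label in {path}")
        out.setdefault(module, set())
        if cat and cat != "nan":
            out[module].add(cat)
    return out


def write_annotations(ann: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("module\tcategory\n")
        for module in sorted(ann, key=str):
            cats = sorted(ann[module]) or [""]
            for cat in cats:
                fh.write(f"{module}\t{cat}\n")


def write_graphml(graph_like, path) -> None:
    """GraphML export for external viewers (gene network or modular map)."""
    g = graph_like.graph if hasattr(graph_like, "graph") else graph_like
    nx.write_graphml(g, path)
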