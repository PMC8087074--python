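"""Synthetic networks, expression matrices, partitions and annotations with
known ground truth.

The generator emulates the scale of a focused co-expression study — a few
hundred genes partitioned into tens of modules per condition — and plants
inter-module coordination so every downstream stage is testable offline:

* intra-module edges are dense and heavy; the number and weight of cross
  edges between a planted pair grow with its coordination strength, so the
  direct statistic (SW) orders pairs as planted;
* mediator genes live in a reserved unassigned pool and are wired to several
  genes in each module of their pair, driving the indirect statistics (PS,
  CT) without polluting third-party pairs;
* annotation sharing between a pair grows with its planted strength, so
  Jaccard similarity tracks coordination;
* condition rewiring has two modes mirroring the two pharmacological
  directions — "aggregate" densifies the module map toward a clique,
  "disperse" scatters a chosen module pair's genes across many modules.

A single integer seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netio import UNASSIGNED, ExpressionMatrix, ModulePartition, WeightedNetwork

__all__ = [
    "PlantedDesign",
    "default_design",
    "core_periphery_design",
    "make_modular_network",
    "make_expression",
    "make_annotations",
    "annotations_matching_js",
    "rewire_condition",
]


@dataclass
class PlantedDesign:
    """Recipe for one synthetic condition.

    module_sizes : gene count per module (labels M01, M02, ... in order)
    coordination : unordered module-pair label tuple -> planted strength in [0, 1]
    mediator_count : pair -> mediator genes wired to both modules; defaults to
        ``round(4 * strength)`` per planted pair
    mediator_pool : extra unassigned genes available as mediators
    intra_weight_dist : (low, high) of intra-module edge weights
    mediator_links : edges from each mediator into each module of its pair
    seed : RNG seed; same seed + design gives byte-identical outputs
    """

    module_sizes: list
    coordination: dict
    mediator_count: dict = field(default_factory=dict)
    mediator_pool: int = 24
    intra_weight_dist: tuple = (0.4, 0.9)
    mediator_links: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every module needs at least 2 genes")
        for pair, s in self.coordination.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"planted strength for {pair} outside [0, 1]: {s}")

    @property
    def module_labels(self) -> list:
        return [f"M{i + 1:02d}" for i in range(len(self.module_sizes))]

    @property
    def n_genes(self) -> int:
        return int(sum(self.module_sizes)) + self.mediator_pool

    def mediators_for(self, pair) -> int:
        key = tuple(sorted(pair))
        if key in self.mediator_count:
            return int(self.mediator_count[key])
        return int(round(4 * self.coordination.get(key, 0.0)))


def default_design(seed: int = 0, n_pairs: int = 10) -> PlantedDesign:
    """The standard recovery design: 374 genes, 20 modules, graded strengths.

    Modules are paired off (M01-M02, M03-M04, ...) so each module takes part
    in exactly one planted pair and strengths cannot interfere; strengths
    step evenly from 0.1 to 1.0 over ``n_pairs`` pairs.
    """
    sizes = list(range(8, 28))  # 20 modules, 8..27 genes, 350 assigned
    labels = [f"M{i + 1:02d}" for i in range(len(sizes))]
    strengths = np.linspace(0.1, 1.0, n_pairs)
    coordination = {
        (labels[2 * i], labels[2 * i + 1]): float(strengths[i]) for i in range(n_pairs)
    }
    return PlantedDesign(module_sizes=sizes, coordination=coordination, seed=seed)


def core_periphery_design(seed: int = 0) -> PlantedDesign:
    """A disease-state archetype: two core modules coordinate strongly with
    each other and moderately with a ring of mid-strength partners, while the
    periphery holds only weak pairwise links.

    The resulting modular map is centralized: the two core modules carry most
    of the betweenness and the heaviest coordination edge, so connector
    detection should recover them and their pair.
    """
    sizes = [20 + (i % 5) for i in range(15)]  # 330 genes in 15 modules
    labels = [f"M{i + 1:02d}" for i in range(len(sizes))]
    coordination: dict = {(labels[0], labels[1]): 1.0}
    for k in range(2, 5):  # satellites reached only through the first core
        coordination[(labels[0], labels[k])] = 0.5
    for k in range(5, 8):  # satellites reached only through the second core
        coordination[(labels[1], labels[k])] = 0.45
    for a, b in ((8, 9), (10, 11), (12, 13)):
        coordination[(labels[a], labels[b])] = 0.15
    return PlantedDesign(
        module_sizes=sizes, coordination=coordination, mediator_pool=44, seed=seed
    )


# ---------------------------------------------------------------------------
# network generation


def _gene_ids(design: PlantedDesign) -> tuple[dict, list]:
    """Deterministic gene naming: module members then the mediator pool."""
    assignment: dict = {}
    idx = 1
    for label, size in zip(design.module_labels, design.module_sizes):
        for _ in range(size):
            assignment[f"g{idx:04d}"] = label
            idx += 1
    pool = []
    for _ in range(design.mediator_pool):
        gene = f"g{idx:04d}"
        assignment[gene] = UNASSIGNED
        pool.append(gene)
        idx += 1
    return assignment, pool


def make_modular_network(design: PlantedDesign):
    """Build a planted condition.

    Returns ``(network, partition, ground_truth)`` where ground_truth is a
    DataFrame with one row per planted pair: module_a, module_b,
    planted_strength, n_cross_edges, n_mediators.
    """
    rng = np.random.default_rng(design.seed)
    assignment, pool = _gene_ids(design)
    part = ModulePartition(assignment)
    members = {m: part.members(m) for m in design.module_labels}
    g = nx.Graph()
    g.add_nodes_from(sorted(assignment))

    lo, hi = design.intra_weight_dist
    for label in design.module_labels:
        genes = members[label]
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                g.add_edge(genes[i], genes[j], weight=float(rng.uniform(lo, hi)))

    pool_cursor = 0
    truth_rows = []
    for pair in sorted(design.coordination):
        x, y = sorted(pair)
        s = design.coordination[pair]
        mx, my = members[x], members[y]
        n_cross = 0
        if s > 0:
            n_cross = max(1, int(round(s * min(len(mx), len(my)))))
            gx = rng.choice(mx, size=n_cross, replace=False)
            gy = rng.choice(my, size=n_cross, replace=False)
            for u, v in zip(gx, gy):
                w = float(np.clip(s * rng.uniform(0.55, 0.85), 0.05, 1.0))
                g.add_edge(u, v, weight=w)
        n_med = design.mediators_for(pair)
        for _ in range(n_med):
            if pool_cursor >= len(pool):
                raise ValueError(
                    "mediator pool exhausted; enlarge PlantedDesign.mediator_pool"
                )
            m = pool[pool_cursor]
            pool_cursor += 1
            k = min(design.mediator_links, len(mx), len(my))
            for u in rng.choice(mx, size=k, replace=False):
                g.add_edge(m, u, weight=float(rng.uniform(0.6, 0.9)))
            for v in rng.choice(my, size=k, replace=False):
                g.add_edge(m, v, weight=float(rng.uniform(0.6, 0.9)))
        truth_rows.append(
            {
                "module_a": x,
                "module_b": y,
                "planted_strength": s,
                "n_cross_edges": n_cross,
                "n_mediators": n_med,
            }
        )
    net = WeightedNetwork(g, weight_floor=0.02)
    truth = pd.DataFrame(
        truth_rows,
        columns=["module_a", "module_b", "planted_strength", "n_cross_edges", "n_mediators"],
    )
    return net, part, truth


def make_expression(
    design: PlantedDesign,
    n_samples: int = 50,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Block-correlated Gaussian expression: one latent factor per module.

    Every gene in a module is ``factor + noise_sd * eps``; unassigned pool
    genes get independent factors.  At ``noise_sd = 0`` within-module
    correlations are exactly 1; soft-threshold adjacency on this matrix
    recovers the planted blocks.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    assignment, pool = _gene_ids(design)
    genes = sorted(assignment)
    factors = {
        label: rng.standard_normal(n_samples) for label in design.module_labels
    }
    rows = []
    for gene in genes:
        label = assignment[gene]
        if label == UNASSIGNED:
            base = rng.standard_normal(n_samples)
        else:
            base = factors[label]
        rows.append(base + noise_sd * rng.standard_normal(n_samples))
    data = pd.DataFrame(
        np.vstack(rows),
        index=genes,
        columns=[f"s{i + 1:02d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(data)


# ---------------------------------------------------------------------------
# annotations


def make_annotations(
    part: ModulePartition,
    coordination: dict,
    n_per_module: int = 8,
    universe: int = 200,
    seed: int = 0,
) -> dict:
    """Category sets whose sharing grows with planted coordination.

    Each module draws ``n_per_module`` categories from a universe large
    enough that chance overlap is rare; then, per planted pair in descending
    strength, ``round(strength * n_per_module)`` of the second module's
    categories are replaced with the first module's so JS rises monotonically
    with strength.
    """
    rng = np.random.default_rng(seed)
    cats = [f"C{i:03d}" for i in range(universe)]
    ann = {
        m: set(rng.choice(cats, size=n_per_module, replace=False))
        for m in part.module_labels
    }
    for pair in sorted(coordination, key=lambda p: (-coordination[p], p)):
        x, y = sorted(pair)
        if x not in ann or y not in ann:
            continue
        k = int(round(coordination[pair] * n_per_module))
        if k == 0:
            continue
        donors = sorted(ann[x])[:k]
        receivers = sorted(ann[y] - set(donors))
        for old, new in zip(receivers[: len(donors)], donors):
            ann[y].discard(old)
            ann[y].add(new)
    return ann


def annotations_matching_js(pair_labels, js_values, union_size: int = 50) -> dict:
    """Deterministic annotation sets hitting target Jaccard values.

    Each pair gets a private category namespace with a fixed union size, an
    intersection of ``round(js * union_size)`` shared categories and the
    remainder split between the two modules.  Useful for planting an exact
    JS-vs-score relationship in calibration tests.
    """
    ann: dict = {}
    for idx, ((a, b), js) in enumerate(zip(pair_labels, js_values)):
        if not (0.0 <= js <= 1.0):
            raise ValueError(f"target JS outside [0, 1]: {js}")
        inter = int(round(js * union_size))
        rest = union_size - inter
        n_a_only = rest // 2
        shared = {f"P{idx:02d}S{i:03d}" for i in range(inter)}
        only_a = {f"P{idx:02d}A{i:03d}" for i in range(n_a_only)}
        only_b = {f"P{idx:02d}B{i:03d}" for i in range(rest - n_a_only)}
        ann.setdefault(a, set()).update(shared | only_a)
        ann.setdefault(b, set()).update(shared | only_b)
    return ann


# ---------------------------------------------------------------------------
# condition rewiring


def rewire_condition(
    net: WeightedNetwork,
    part: ModulePartition,
    mode: str,
    intensity: float,
    seed: int = 0,
    pmp=None,
    n_landing: int = 4,
):
    """Derive a perturbed condition from a reference one.

    mode="aggregate": add cross edges between every module pair with
    probability ``intensity`` per missing gene pair (clipped), pushing the
    module map toward a clique.  mode="disperse": move a fraction
    ``intensity`` of the given module pair's genes round-robin into
    ``n_landing`` other modules and upweight the surviving cross edges.

    Returns ``(network, partition, ground_truth)``; for disperse the ground
    truth maps each moved gene to its landing module.  ``intensity = 0``
    returns unchanged copies.
    """
    if not (0.0 <= intensity <= 1.0):
        raise ValueError(f"intensity must lie in [0, 1], got {intensity}")
    rng = np.random.default_rng(seed)
    g = net.graph.copy()
    assignment = dict(part.assignment)

    if mode == "aggregate":
        labels = part.module_labels
        members = {m: part.members(m) for m in labels}
        added = 0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                mx, my = members[labels[i]], members[labels[j]]
                # a handful of draws per pair keeps the map dense but the
                # gene graph sparse
                n_draw = max(1, int(round(intensity * 4)))
                if intensity == 0:
                    continue
                for _ in range(n_draw):
                    u = mx[int(rng.integers(len(mx)))]
                    v = my[int(rng.integers(len(my)))]
                    if not g.has_edge(u, v):
                        g.add_edge(u, v, weight=float(rng.uniform(0.3, 0.8)))
                        added += 1
        truth = {"mode": "aggregate", "intensity": intensity, "edges_added": added}
        return WeightedNetwork(g, net.weight_floor), ModulePartition(assignment), truth

    if mode == "disperse":
        if pmp is None:
            raise ValueError("disperse mode needs the module pair to scatter")
        a, b = sorted(map(str, pmp))
        genes = part.members(a) + part.members(b)
        landing_pool = [m for m in part.module_labels if m not in (a, b)]
        if n_landing > len(landing_pool):
            raise ValueError(
                f"cannot land in {n_landing} modules; only {len(landing_pool)} available"
            )
        landing_labels = landing_pool[:n_landing]
        n_move = int(round(intensity * len(genes)))
        moved = list(rng.permutation(genes)[:n_move])
        gene_to_landing = {}
        for i, gene in enumerate(sorted(moved)):
            dest = landing_labels[i % n_landing]
            assignment[gene] = dest
            gene_to_landing[gene] = dest
        # decouple: drop the pair's direct edges, widen what survives elsewhere
        for u, v in list(g.edges):
            mu, mv = part.module_of(u), part.module_of(v)
            if {mu, mv} == {a, b}:
                g.remove_edge(u, v)
            elif mu != mv and mu is not None and mv is not None:
                g[u][v]["weight"] = float(min(1.0, g[u][v]["weight"] * (1 + intensity)))
        truth = {
            "mode": "disperse",
            "intensity": intensity,
            "pmp": (a, b),
            "landing_labels": landing_labels,
            "gene_to_landing": gene_to_landing,
        }
        return WeightedNetwork(g, net.weight_floor), ModulePartition(assignment), truth

    raise ValueError(f"unknown rewiring mode {mode!r}; use 'aggregate' or 'disperse'")
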