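"""Connector-module detection and pathological-pair dissociation.

Connectors — modules that bridge communities in the modular map — are called
by three independent criteria and intersected:

1. top 10% of modules by normalized betweenness centrality (ties at the cut
   included);
2. VRCD: delete each module in turn and form η = Δs/Δt, the ratio of the
   relative change in characteristic path length to the relative change in
   density; modules with η above twice the map average respond most strongly
   and are called (a clique yields equal η for every module and hence an
   empty set);
3. edge weight: modules incident to at least one map edge heavier than 0.1.

The consensus pair with the strongest coordination edge is the pathological
module pair (PMP).  Its dissociation into another condition's partition is
summarized by the dissociation rate ``DR = (n_B/n_A) · (N_A/N_B)`` where
``n`` counts the modules holding the pair's genes and ``N`` the condition's
total module count, before (A) and after (B).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .modmap import ModularMap, characteristic_path_length
from .netio import ModulePartition

__all__ = [
    "ConnectorReport",
    "DissociationResult",
    "betweenness_connectors",
    "vrcd",
    "weight_connectors",
    "consensus_and_pmp",
    "dissociation_rate",
    "trace_pmp",
    "LOST_LABEL",
]

#: Reserved landing label for PMP genes absent from the other partition.
LOST_LABEL = "lost"


@dataclass
class ConnectorReport:
    by_betweenness: set
    by_vrcd: set
    by_weight: set
    eta: dict  # module -> η (NaN when undefined)
    consensus: set = field(init=False)
    pmp: tuple | None = None

    def __post_init__(self) -> None:
        self.consensus = self.by_betweenness & self.by_vrcd & self.by_weight


@dataclass
class DissociationResult:
    n_a: int
    n_b: int
    big_n_a: int
    big_n_b: int
    dr: float
    dispersion: dict  # landing module -> fraction of placed PMP genes
    lost: int = 0


def betweenness_connectors(mmap: ModularMap, top_fraction: float = 0.10) -> set:
    """Top ``ceil(top_fraction * n)`` modules by normalized betweenness.

    Modules tied with the score at the cut are all included (warned when the
    map is degenerate and every betweenness is equal).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    g = mmap.graph
    n = g.number_of_nodes()
    if n == 0:
        return set()
    bc = nx.betweenness_centrality(g, normalized=True)
    k = math.ceil(top_fraction * n)
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], str(kv[0])))
    cut_score = ranked[k - 1][1]
    chosen = {m for m, s in ranked if s > cut_score or np.isclose(s, cut_score)}
    if len(set(bc.values())) == 1:
        warnings.warn(
            "all betweenness values equal; the top-fraction cut is degenerate",
            stacklevel=2,
        )
    # ties at the cut expand the set beyond k; below-cut modules never enter
    return {m for m in chosen if bc[m] >= cut_score - 1e-15}


def vrcd(mmap: ModularMap, multiplier: float = 2.0):
    """Variation of the ratio of characteristic path length to density.

    Deleting module *m* gives Δs = (CPL_a − CPL_o)/CPL_o and
    Δt = (D_a − D_o)/D_o, with CPL taken over the connected pairs that remain.
    η_m = Δs/Δt; modules with Δt = 0 (or no surviving connected pair) have
    undefined η and are excluded from the mean.  Connectors are the modules
    with η above ``multiplier`` × mean(η); when every defined η is equal — the
    clique-like case — the connector set is empty.

    Returns ``(eta, connectors)`` with η per module (NaN when undefined).
    """
    g = mmap.graph
    if g.number_of_nodes() < 3:
        raise ValueError("VRCD needs a map with at least 3 modules")
    cpl_o = characteristic_path_length(g)
    d_o = nx.density(g)
    eta: dict = {}
    for m in sorted(g.nodes, key=str):
        h = g.copy()
        h.remove_node(m)
        d_a = nx.density(h)
        cpl_a = characteristic_path_length(h)
        if d_o == 0 or not np.isfinite(cpl_a) or not np.isfinite(cpl_o):
            eta[m] = float("nan")
            continue
        delta_t = (d_a - d_o) / d_o
        if delta_t == 0:
            eta[m] = float("nan")
            continue
        delta_s = (cpl_a - cpl_o) / cpl_o
        eta[m] = delta_s / delta_t
    defined = {m: v for m, v in eta.items() if np.isfinite(v)}
    if not defined:
        return eta, set()
    values = np.array(list(defined.values()))
    if np.allclose(values, values[0]):
        return eta, set()
    cutoff = multiplier * values.mean()
    connectors = {m for m, v in defined.items() if v > cutoff}
    return eta, connectors


def weight_connectors(mmap: ModularMap, cutoff: float = 0.1) -> set:
    """Modules incident to at least one map edge with weight > cutoff."""
    out: set = set()
    for u, v, w in mmap.graph.edges(data="weight"):
        if w > cutoff:
            out.add(u)
            out.add(v)
    return out


def consensus_and_pmp(
    mmap: ModularMap,
    top_fraction: float = 0.10,
    vrcd_multiplier: float = 2.0,
    weight_cutoff: float = 0.1,
) -> ConnectorReport:
    """Run all three detectors, intersect, and pick the pathological pair.

    The PMP is the consensus pair joined by the heaviest coordination edge;
    it is None when fewer than two consensus modules share a map edge.
    """
    by_b = betweenness_connectors(mmap, top_fraction)
    eta, by_v = vrcd(mmap, vrcd_multiplier)
    by_w = weight_connectors(mmap, weight_cutoff)
    report = ConnectorReport(by_betweenness=by_b, by_vrcd=by_v, by_weight=by_w, eta=eta)
    best, best_w = None, -np.inf
    for u, v, w in mmap.graph.edges(data="weight"):
        if u in report.consensus and v in report.consensus and w > best_w:
            best, best_w = tuple(sorted((u, v), key=str)), w
    report.pmp = best
    return report


def dissociation_rate(n_a: int, n_b: int, big_n_a: int, big_n_b: int) -> float:
    """DR = (n_B / n_A) · (N_A / N_B)."""
    for name, v in (("n_A", n_a), ("n_B", n_b), ("N_A", big_n_a), ("N_B", big_n_b)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    return (n_b / n_a) * (big_n_a / big_n_b)


def trace_pmp(
    part_ref: ModulePartition,
    part_other: ModulePartition,
    pmp,
) -> DissociationResult:
    """Follow the PMP genes of the reference partition into another condition.

    Each gene of the two PMP modules is looked up in ``part_other``; genes
    absent there are tallied under the reserved "lost" label and excluded
    from the landing-module count.  Dispersion fractions are over the placed
    genes and sum to 1.
    """
    a, b = sorted(map(str, pmp))
    genes = part_ref.members(a) + part_ref.members(b)
    if not genes:
        raise ValueError(f"PMP modules {a!r}/{b!r} hold no genes")
    landing: dict = {}
    lost = 0
    for gene in genes:
        dest = part_other.module_of(gene)
        if dest is None:
            lost += 1
            warnings.warn(f"PMP gene {gene!r} absent from the other partition", stacklevel=2)
            continue
        landing[dest] = landing.get(dest, 0) + 1
    placed = sum(landing.values())
    if placed == 0:
        raise ValueError("no PMP gene could be placed in the other partition")
    dispersion = {m: c / placed for m, c in sorted(landing.items(), key=lambda kv: str(kv[0]))}
    n_b = len(landing)
    big_n_a = part_ref.n_modules
    big_n_b = part_other.n_modules
    dr = dissociation_rate(2, n_b, big_n_a, big_n_b)
    return DissociationResult(
        n_a=2,
        n_b=n_b,
        big_n_a=big_n_a,
        big_n_b=big_n_b,
        dr=dr,
        dispersion=dispersion,
        lost=lost,
    )
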