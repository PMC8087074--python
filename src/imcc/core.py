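"""Inter-module coordination scoring.

Three pairwise statistics are computed for every module pair that is linked
either directly or through a shared external partner:

* **SW** — sum of weights of the edges spanning the two modules (direct
  inter-module connection);
* **PS** — path strength: over every 3-node path *o–m–e* with the outset in
  one module, the end in the other and the mediator outside both, the product
  of the mediator's weighted probabilities of choosing each endpoint,
  ``(W_mo / W_m) * (W_me / W_m)``;
* **CT** — consistency score: for every gene *i* outside both modules,
  ``min(CM_x,i - (S/C)*CL_i, CM_y,i - (T/C)*CL_i) * (CM_x,i * CM_y,i / CL_i) * W_i``,
  a shared-partner statistic that contrasts a gene's observed links into each
  module with the null expectation from its degree.

SW and PS are screened with an upper-tail hypergeometric test (observed
within-pair count against the condition-wide totals), CT with a fixed cutoff.
Surviving SW and CT are min-max normalized across pairs and integrated as
``IMCC1 = alpha*SW' + beta*CT'`` with ``alpha + beta = 1`` and ratio
``rho = alpha/beta``; at the calibrated ``rho = 1`` the final score reduces to
``IMCC = SW' + CT'``.  ``IMCC2 = SW + PS`` integrates the two same-dimension
statistics without weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .netio import UNASSIGNED, ModulePartition, WeightedNetwork

__all__ = [
    "ScreeningConfig",
    "sum_of_weights",
    "hypergeom_upper_tail",
    "path_strength",
    "consistency_score",
    "minmax_normalize",
    "integrate_imcc1",
    "integrate_imcc2",
    "screen_sw",
    "screen_ps",
    "screen_ct",
    "compute_imcc",
    "score_condition",
    "write_pair_scores",
    "read_pair_scores",
]

#: Stable column order of the pair-score table.
PAIR_COLUMNS = [
    "module_a",
    "module_b",
    "sw",
    "p_sw",
    "sw_valid",
    "ps",
    "p_ps",
    "ps_valid",
    "ct",
    "ct_valid",
    "sw_norm",
    "ct_norm",
    "imcc1",
    "imcc2",
    "imcc",
]


@dataclass
class ScreeningConfig:
    """Cutoffs for parameter screening and the IMCC1 weighting ratio.

    p_cutoff : SW/PS hypergeometric significance level (valid when p < cutoff)
    ct_cutoff : CT validity threshold (valid when ct > cutoff, strict)
    rho : alpha/beta ratio for IMCC1 (alpha = rho/(1+rho))
    require_both : final IMCC only for pairs where both SW and CT survived
        screening; if False, a single surviving parameter is used with the
        other set to 0 (sensitivity-analysis mode).
    """

    p_cutoff: float = 0.05
    ct_cutoff: float = 10.0
    rho: float = 1.0
    require_both: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError(f"p_cutoff must lie in (0, 1), got {self.p_cutoff}")
        if self.ct_cutoff < 0:
            raise ValueError(f"ct_cutoff must be >= 0, got {self.ct_cutoff}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")


def _pair_key(a, b) -> tuple:
    """Canonical (lexicographic) ordering of an unordered module pair."""
    a, b = str(a), str(b)
    if a == b:
        raise ValueError(f"a module pair needs two distinct modules, got {a!r} twice")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# raw statistics


def sum_of_weights(net: WeightedNetwork, part: ModulePartition, pair) -> float:
    """SW: total weight of edges with one endpoint in each module."""
    x, y = _pair_key(*pair)
    mx, my = set(part.members(x)), set(part.members(y))
    total = 0.0
    for u in mx:
        if u not in net.graph:
            continue
        for v, d in net.graph[u].items():
            if v in my:
                total += d["weight"]
    return total


def hypergeom_upper_tail(x: int, n: int, M: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[K >= x].

    K counts successes in ``n`` draws without replacement from a population of
    ``N`` containing ``M`` successes.  ``x = 0`` returns exactly 1.  Values
    that underflow the linear scale are recovered from the log tail.
    """
    if not (0 <= x <= n <= N):
        raise ValueError(f"need 0 <= x <= n <= N, got x={x}, n={n}, N={N}")
    if not (0 <= M <= N):
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if x == 0:
        return 1.0
    if x > min(n, M):  # beyond the support: the tail is empty
        return 0.0
    p = float(hypergeom.sf(x - 1, N, M, n))
    if p == 0.0:
        p = float(np.exp(hypergeom.logsf(x - 1, N, M, n)))
    return min(p, 1.0)


def path_strength(net: WeightedNetwork, part: ModulePartition, pair) -> float:
    """PS: sum over mediators m of (sum_o W_mo)(sum_e W_me) / W_m**2.

    Mediators are genes outside both modules adjacent to at least one gene in
    each; the double sum over endpoints factorizes per mediator.
    """
    x, y = _pair_key(*pair)
    mx, my = set(part.members(x)), set(part.members(y))
    excluded = mx | my
    total = 0.0
    for m in net.graph.nodes:
        if m in excluded:
            continue
        s_o = s_e = 0.0
        for v, d in net.graph[m].items():
            if v in mx:
                s_o += d["weight"]
            elif v in my:
                s_e += d["weight"]
        if s_o > 0.0 and s_e > 0.0:
            w_m = net.weighted_degree(m)
            total += (s_o / w_m) * (s_e / w_m)
    return total


def consistency_score(net: WeightedNetwork, part: ModulePartition, pair) -> float:
    """CT: shared-partner consistency score of a module pair.

    Sums, over every network gene outside both modules with at least one link
    into each, the degree-centered minimum enrichment times the link product
    over degree, scaled by the gene's weighted degree.
    """
    x, y = _pair_key(*pair)
    mx, my = set(part.members(x)), set(part.members(y))
    c_total = net.n_nodes
    if c_total == 0:
        return 0.0
    s, t = len(mx), len(my)
    total = 0.0
    for i in net.graph.nodes:
        if i in mx or i in my:
            continue
        cl = net.degree(i)
        if cl == 0:
            continue
        cm_x = cm_y = 0
        for v in net.graph[i]:
            if v in mx:
                cm_x += 1
            elif v in my:
                cm_y += 1
        if cm_x == 0 or cm_y == 0:
            continue
        centered = min(cm_x - (s / c_total) * cl, cm_y - (t / c_total) * cl)
        total += centered * (cm_x * cm_y / cl) * net.weighted_degree(i)
    return total


# ---------------------------------------------------------------------------
# normalization and integration


def minmax_normalize(values) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant list maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty list")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def integrate_imcc1(sw_norm: float, ct_norm: float, rho: float) -> float:
    """Weighted integration alpha*SW' + beta*CT' with rho = alpha/beta."""
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    alpha = rho / (1.0 + rho)
    beta = 1.0 / (1.0 + rho)
    return alpha * sw_norm + beta * ct_norm


def integrate_imcc2(sw: float, ps: float) -> float:
    """Unweighted integration of the two same-dimension statistics."""
    return sw + ps


# ---------------------------------------------------------------------------
# screening

def _node_profiles(net: WeightedNetwork, part: ModulePartition):
    """Per-gene link counts and weight sums into each module."""
    module_of = {g: part.module_of(g) for g in net.graph.nodes}
    profiles = {}
    for g in net.graph.nodes:
        counts: dict = {}
        wsums: dict = {}
        for v, d in net.graph[g].items():
            m = module_of.get(v)
            if m is None or m == UNASSIGNED:
                continue
            counts[m] = counts.get(m, 0) + 1
            wsums[m] = wsums.get(m, 0.0) + d["weight"]
        profiles[g] = (counts, wsums, net.degree(g), net.weighted_degree(g))
    return module_of, profiles


def _base_table(net: WeightedNetwork, part: ModulePartition) -> pd.DataFrame:
    """Raw SW/PS/CT and the hypergeometric inputs per scored module pair.

    A pair is scored when it has at least one cross edge or one shared
    external partner.  The condition-wide hypergeometric totals (observed and
    possible cross edges, observed and candidate mediators) are accumulated
    over *all* module pairs and stored in ``DataFrame.attrs`` — the
    enrichment of a pair is judged against the whole map, not only against
    the scored pairs.
    """
    labels = part.module_labels
    members = {m: part.members(m) for m in labels}
    sizes = {m: len(members[m]) for m in labels}
    c_total = net.n_nodes
    module_of, profiles = _node_profiles(net, part)
    # genes grouped by own module for the cross-edge sums
    rows = []
    tot_edges = tot_possible = tot_mediators = tot_candidates = 0
    for x, y in combinations(labels, 2):
        s, t = sizes[x], sizes[y]
        n_edges = 0
        sw = 0.0
        for u in members[x]:
            counts, wsums, _, _ = profiles.get(u, ({}, {}, 0, 0.0))
            n_edges += counts.get(y, 0)
            sw += wsums.get(y, 0.0)
        ps = ct = 0.0
        n_med = n_cand = 0
        for g, (counts, wsums, cl, w_i) in profiles.items():
            m = module_of.get(g)
            if m == x or m == y:
                continue
            cx, cy = counts.get(x, 0), counts.get(y, 0)
            if cx or cy:
                n_cand += 1
            if cx and cy:
                n_med += 1
                ps += (wsums[x] / w_i) * (wsums[y] / w_i)
                centered = min(cx - (s / c_total) * cl, cy - (t / c_total) * cl)
                ct += centered * (cx * cy / cl) * w_i
        tot_edges += n_edges
        tot_possible += s * t
        tot_mediators += n_med
        tot_candidates += n_cand
        if n_edges == 0 and n_med == 0:
            continue
        rows.append(
            {
                "module_a": x,
                "module_b": y,
                "sw": sw,
                "ps": ps,
                "ct": ct,
                "_n_cross_edges": n_edges,
                "_n_possible_edges": s * t,
                "_n_mediators": n_med,
                "_n_candidates": n_cand,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "module_a",
            "module_b",
            "sw",
            "ps",
            "ct",
            "_n_cross_edges",
            "_n_possible_edges",
            "_n_mediators",
            "_n_candidates",
        ],
    )
    table.attrs["total_cross_edges"] = tot_edges
    table.attrs["total_possible_edges"] = tot_possible
    table.attrs["total_mediators"] = tot_mediators
    table.attrs["total_candidates"] = tot_candidates
    return table


def screen_sw(table: pd.DataFrame, cfg: ScreeningConfig) -> pd.DataFrame:
    """Hypergeometric screen of SW (edge-based parameterization).

    Per pair: x = observed cross edges, n = possible cross pairs |Mx|*|My|;
    condition-wide: M = total observed inter-module edges, N = total possible
    cross-module gene pairs, both summed over all module pairs.
    """
    table = table.copy()
    M = int(table.attrs.get("total_cross_edges", table["_n_cross_edges"].sum()))
    N = int(table.attrs.get("total_possible_edges", table["_n_possible_edges"].sum()))
    p_vals, valid = [], []
    for x, n in zip(table["_n_cross_edges"], table["_n_possible_edges"]):
        if x == 0:
            p_vals.append(np.nan)
            valid.append(False)
            continue
        p = hypergeom_upper_tail(int(x), int(n), M, N)
        p_vals.append(p)
        valid.append(p < cfg.p_cutoff)
    table["p_sw"] = p_vals
    table["sw_valid"] = valid
    return table


def screen_ps(table: pd.DataFrame, cfg: ScreeningConfig) -> pd.DataFrame:
    """Hypergeometric screen of PS (node-based parameterization).

    Per pair: x = observed mediators, n = candidate mediators (external genes
    adjacent to at least one of the two modules); condition-wide: M = total
    observed mediators, N = total candidates, summed over all module pairs.
    """
    table = table.copy()
    M = int(table.attrs.get("total_mediators", table["_n_mediators"].sum()))
    N = int(table.attrs.get("total_candidates", table["_n_candidates"].sum()))
    p_vals, valid = [], []
    for x, n in zip(table["_n_mediators"], table["_n_candidates"]):
        if x == 0:
            p_vals.append(np.nan)
            valid.append(False)
            continue
        p = hypergeom_upper_tail(int(x), int(n), M, N)
        p_vals.append(p)
        valid.append(p < cfg.p_cutoff)
    table["p_ps"] = p_vals
    table["ps_valid"] = valid
    return table


def screen_ct(table: pd.DataFrame, cfg: ScreeningConfig) -> pd.DataFrame:
    """CT validity screen: strictly greater than the cutoff."""
    table = table.copy()
    table["ct_valid"] = table["ct"] > cfg.ct_cutoff
    return table


def compute_imcc(table: pd.DataFrame, cfg: ScreeningConfig) -> pd.DataFrame:
    """Normalize, integrate and rank the screened table.

    SW and CT are min-max normalized across all scored pairs of the
    condition.  IMCC1 and the final IMCC are assigned to pairs passing both
    the SW and CT screens (unless ``cfg.require_both`` is off), IMCC2 to
    pairs passing the SW and PS screens.  Rows sort by descending IMCC with
    ties broken by SW then pair label.
    """
    table = table.copy()
    table["sw_norm"] = minmax_normalize(table["sw"])
    table["ct_norm"] = minmax_normalize(table["ct"])

    if cfg.require_both:
        sw_part = np.where(table["sw_valid"], table["sw_norm"], np.nan)
        ct_part = np.where(table["ct_valid"], table["ct_norm"], np.nan)
    else:
        sw_part = np.where(table["sw_valid"], table["sw_norm"], 0.0)
        ct_part = np.where(table["ct_valid"], table["ct_norm"], 0.0)
        neither = ~(table["sw_valid"] | table["ct_valid"])
        sw_part = np.where(neither, np.nan, sw_part)
        ct_part = np.where(neither, np.nan, ct_part)
    table["imcc1"] = [
        integrate_imcc1(s, c, cfg.rho) if np.isfinite(s) and np.isfinite(c) else np.nan
        for s, c in zip(sw_part, ct_part)
    ]
    table["imcc"] = sw_part + ct_part

    both2 = table["sw_valid"] & table["ps_valid"]
    table["imcc2"] = np.where(both2, table["sw"] + table["ps"], np.nan)

    table = table.sort_values(
        by=["imcc", "sw", "module_a", "module_b"],
        ascending=[False, False, True, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def score_condition(
    net: WeightedNetwork, part: ModulePartition, cfg: ScreeningConfig | None = None
) -> pd.DataFrame:
    """End-to-end per-condition pipeline: raw statistics, screening,
    within-condition normalization and integration.

    Returns one row per scored module pair with the stable column order of
    ``PAIR_COLUMNS`` (internal counting columns retained with a ``_`` prefix).
    """
    cfg = cfg or ScreeningConfig()
    table = _base_table(net, part)
    if table.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    table = screen_sw(table, cfg)
    table = screen_ps(table, cfg)
    table = screen_ct(table, cfg)
    table = compute_imcc(table, cfg)
    extras = [c for c in table.columns if c.startswith("_")]
    return table[PAIR_COLUMNS + extras]


def write_pair_scores(table: pd.DataFrame, path) -> None:
    cols = [c for c in PAIR_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pair_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
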