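"""Calibration of the integration weight against functional annotation.

The weighting ratio ``rho`` and the integration scheme are chosen by fitting
the coordination score against the Jaccard similarity of the two modules'
functional category sets, ``JS = |A ∩ B| / |A ∪ B|`` — module pairs sharing
annotated function are expected to coordinate more strongly.  Candidate
curve-estimation models are the usual four (linear, logarithmic, power,
exponential); the ratio maximizing the logarithmic-model R² wins, with ties
going to the ratio closest to 1.

IMASP (inter-module average shortest path) provides a purely topological
cross-check: the mean gene-level shortest-path hop count between the members
of two modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .core import integrate_imcc1
from .netio import ModulePartition, WeightedNetwork

__all__ = [
    "FitResult",
    "jaccard_similarity",
    "fit_curve",
    "remove_outliers",
    "fit_with_outlier_removal",
    "pair_jaccard",
    "scan_rho",
    "compare_integrations",
    "imasp",
]

MODELS = ("linear", "logarithmic", "power", "exponential")


@dataclass
class FitResult:
    model_name: str
    coefficients: tuple  # (a, b): slope-like and intercept-like parameter
    r_squared: float
    n_points: int
    outliers_removed: int = 0

    def predict(self, x) -> np.ndarray:
        return _predict(self.model_name, self.coefficients, np.asarray(x, dtype=float))


def jaccard_similarity(a, b) -> float:
    """JS = |A ∩ B| / |A ∪ B| of two category sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# curve fitting


def _design(model: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(transformed x, transformed y mask requirement) for the linearized fit."""
    if model == "linear":
        return x, None
    if model == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic model requires strictly positive x")
        return np.log(x), None
    if model == "power":
        if np.any(x <= 0):
            raise ValueError("power model requires strictly positive x")
        return np.log(x), "log"
    if model == "exponential":
        return x, "log"
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def _predict(model: str, coef, x: np.ndarray) -> np.ndarray:
    a, b = coef
    if model == "linear":
        return a * x + b
    if model == "logarithmic":
        return a * np.log(x) + b
    if model == "power":
        return b * x**a
    if model == "exponential":
        return b * np.exp(a * x)
    raise ValueError(f"unknown model {model!r}")


def fit_curve(x, y, model: str = "logarithmic") -> FitResult:
    """Least-squares fit of one of the four curve-estimation models.

    Models: linear ``y = a x + b``; logarithmic ``y = a ln x + b``; power
    ``y = b x^a`` (fit log-log); exponential ``y = b e^{a x}`` (fit semilog).
    R² = 1 − SS_res/SS_tot is evaluated on the original y scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values equal")
    tx, y_transform = _design(model, x)
    if y_transform == "log":
        if np.any(y <= 0):
            raise ValueError(f"{model} model requires strictly positive y")
        ty = np.log(y)
    else:
        ty = y
    slope, intercept = np.polyfit(tx, ty, 1)
    if y_transform == "log":
        coef = (float(slope), float(math.exp(intercept)))
    else:
        coef = (float(slope), float(intercept))
    pred = _predict(model, coef, x)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FitResult(model, coef, float(r2), int(x.size))


def remove_outliers(x, y, model: str = "logarithmic", threshold: float = 3.0):
    """Drop points with |externally studentized residual| > threshold.

    One pass under the current model's linearized regression; refuses (returns
    the input unchanged) when removal would leave fewer than 3 points.
    Returns ``(x_kept, y_kept, n_removed)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:  # cannot both remove and keep >= 3
        return x, y, 0
    tx, y_transform = _design(model, x)
    ty = np.log(y) if y_transform == "log" else y
    ols = sm.OLS(ty, sm.add_constant(tx)).fit()
    if ols.resid.std() < 1e-12:  # (near-)perfect fit: nothing to remove
        return x, y, 0
    with np.errstate(invalid="ignore", divide="ignore"):
        student = OLSInfluence(ols).resid_studentized_external
    keep = ~(np.abs(student) > threshold)  # non-finite values are kept
    if keep.sum() < 3 or keep.all():
        return x, y, 0
    return x[keep], y[keep], int((~keep).sum())


def fit_with_outlier_removal(
    x, y, model: str = "logarithmic", threshold: float = 3.0
) -> FitResult:
    """Fit, drop gross outliers once, refit; records the removal count."""
    x_kept, y_kept, removed = remove_outliers(x, y, model=model, threshold=threshold)
    result = fit_curve(x_kept, y_kept, model=model)
    result.outliers_removed = removed
    return result


# ---------------------------------------------------------------------------
# rho scan and scheme comparison


def pair_jaccard(table: pd.DataFrame, annotations: dict) -> pd.Series:
    """JS per table row; NaN when a module is unannotated or both sets empty."""
    js = []
    for a, b in zip(table["module_a"], table["module_b"]):
        sa = annotations.get(str(a))
        sb = annotations.get(str(b))
        if sa is None or sb is None or not (set(sa) | set(sb)):
            js.append(np.nan)
        else:
            js.append(jaccard_similarity(sa, sb))
    return pd.Series(js, index=table.index, name="js")


def _fit_js_against(score: pd.Series, js: pd.Series, model: str, threshold: float):
    mask = np.isfinite(score) & np.isfinite(js) & (score > 0)
    if mask.sum() < 3:
        return None
    return fit_with_outlier_removal(
        score[mask].to_numpy(), js[mask].to_numpy(), model=model, threshold=threshold
    )


def scan_rho(
    table: pd.DataFrame,
    annotations: dict,
    grid=(1 / 10, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0, 10.0),
    model: str = "logarithmic",
    outlier_threshold: float = 3.0,
):
    """Profile the annotation fit across the weighting-ratio grid.

    For each rho the integrated score ``alpha*SW' + beta*CT'`` is recomputed
    for pairs that passed both screens, JS is fit against it with the named
    model (outliers removed once), and the best rho is the grid argmax of R²
    with ties resolved toward rho = 1.

    Returns ``(best_rho, profile)`` where profile is a DataFrame with columns
    rho, r_squared, n_points, outliers_removed.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("rho grid must be non-empty")
    js = pair_jaccard(table, annotations)
    both = table["sw_valid"] & table["ct_valid"]
    rows = []
    for rho in grid:
        score = pd.Series(
            [
                integrate_imcc1(s, c, rho) if ok else np.nan
                for s, c, ok in zip(table["sw_norm"], table["ct_norm"], both)
            ],
            index=table.index,
        )
        fit = _fit_js_against(score, js, model, outlier_threshold)
        rows.append(
            {
                "rho": rho,
                "r_squared": np.nan if fit is None else fit.r_squared,
                "n_points": 0 if fit is None else fit.n_points,
                "outliers_removed": 0 if fit is None else fit.outliers_removed,
            }
        )
    profile = pd.DataFrame(rows)
    if not np.isfinite(profile["r_squared"]).any():
        raise ValueError("insufficient annotated pairs: no rho could be fit")
    best_r2 = profile["r_squared"].max()
    tied = profile[np.isclose(profile["r_squared"], best_r2)]["rho"]
    best_rho = min(tied, key=lambda r: (abs(math.log(r)), r))
    return best_rho, profile


def compare_integrations(
    table: pd.DataFrame,
    annotations: dict,
    best_rho: float = 1.0,
    model: str = "logarithmic",
    outlier_threshold: float = 3.0,
) -> dict:
    """R² of JS fit against raw SW, IMCC1(best rho) and IMCC2.

    All three use the same model family and outlier rule.  A competitor whose
    fit is infeasible (fewer than 3 usable pairs) is reported as None.
    """
    js = pair_jaccard(table, annotations)
    both = table["sw_valid"] & table["ct_valid"]
    imcc1 = pd.Series(
        [
            integrate_imcc1(s, c, best_rho) if ok else np.nan
            for s, c, ok in zip(table["sw_norm"], table["ct_norm"], both)
        ],
        index=table.index,
    )
    competitors = {
        "sw": table["sw"],
        "imcc1": imcc1,
        "imcc2": table["imcc2"] if "imcc2" in table else pd.Series(np.nan, index=table.index),
    }
    fits = {
        name: _fit_js_against(score, js, model, outlier_threshold)
        for name, score in competitors.items()
    }
    r2 = {name: (None if f is None else f.r_squared) for name, f in fits.items()}
    scored = {k: v for k, v in r2.items() if v is not None}
    winner = max(scored, key=scored.get) if scored else None
    return {"model": model, "r_squared": r2, "fits": fits, "winner": winner}


# ---------------------------------------------------------------------------
# IMASP


def imasp(
    net: WeightedNetwork,
    part: ModulePartition,
    pair,
    weighted: bool = False,
) -> float:
    """Inter-module average shortest path between two modules' genes.

    Mean shortest-path length over all cross-module gene pairs; hop counts by
    default, ``1/weight`` edge lengths when ``weighted``.  Unreachable pairs
    are excluded from the mean; NaN when no cross pair is reachable.
    """
    a, b = sorted(map(str, pair))
    mx, my = part.members(a), part.members(b)
    g = net.graph
    if weighted:
        g = g.copy()
        for u, v, w in g.edges(data="weight"):
            g[u][v]["length"] = 1.0 / w
    total, count = 0.0, 0
    for u in mx:
        if u not in g:
            continue
        if weighted:
            dist = nx.single_source_dijkstra_path_length(g, u, weight="length")
        else:
            dist = nx.single_source_shortest_path_length(g, u)
        for v in my:
            if v in dist:
                total += dist[v]
                count += 1
    return total / count if count else float("nan")
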