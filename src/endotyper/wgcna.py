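"""Weighted correlation network analysis over the biomarker panel.

Implements the standard construction: unsigned soft-thresholded adjacency
a_ij = |cor(x_i, x_j)|^beta with the power picked by the scale-free topology
criterion, topological overlap similarity, average-linkage clustering on
1 - TOM, and a fixed-height cut scan standing in for the dynamic tree cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = ["ModuleSet", "pick_soft_power", "compute_tom", "detect_modules",
           "endotype_module_summary", "scale_free_fit"]


def _check_expr(expr) -> tuple[np.ndarray, list]:
    if isinstance(expr, pd.DataFrame):
        names = list(expr.columns)
        X = expr.to_numpy(dtype=float)
    else:
        X = np.asarray(expr, dtype=float)
        names = [f"v{i}" for i in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix must be finite")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant biomarkers cannot enter the network: {bad}")
    return X, names


def _abs_cor(X) -> np.ndarray:
    C = np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(C, 0.0)
    return C


def _adjacency(X, beta) -> np.ndarray:
    return _abs_cor(X) ** beta


def scale_free_fit(connectivity, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k regression over connectivity bins."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    lx = np.log10(centers[keep])
    ly = np.log10(counts[keep] / counts.sum())
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / ss_tot)


def pick_soft_power(expr, powers=range(1, 21), r2_threshold: float = 0.8):
    """Smallest power with scale-free fit R^2 >= threshold.

    Falls back (flagged) to the power with maximal R^2 when no candidate
    reaches the threshold — typical for small designed panels whose degree
    distribution is not scale-free.
    """
    X, _ = _check_expr(expr)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 biomarkers")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    rows = []
    for beta in powers:
        A = _adjacency(X, beta)
        k = A.sum(axis=1)
        rows.append({"power": int(beta), "r2": scale_free_fit(k),
                     "mean_connectivity": float(k.mean())})
    fits = pd.DataFrame(rows)
    ok = fits[fits.r2 >= r2_threshold]
    if len(ok):
        beta = int(ok.power.iloc[0])
        fallback = False
    else:
        beta = int(fits.loc[fits.r2.idxmax(), "power"])
        fallback = True
    return beta, fits, fallback


@dataclass
class ModuleSet:
    beta_power: int
    adjacency: np.ndarray
    tom: np.ndarray
    connectivity: np.ndarray
    names: list
    abs_cor: np.ndarray = field(default=None, repr=False)
    n_samples: int = 0
    module_map: pd.Series = field(default=None)   # name -> module id (0 unassigned)
    fit_table: pd.DataFrame = field(default=None)
    power_fallback: bool = False

    @property
    def n_modules(self) -> int:
        if self.module_map is None:
            return 0
        return int((pd.unique(self.module_map[self.module_map > 0])).size)


def compute_tom(expr, beta_power: int) -> ModuleSet:
    """Unsigned adjacency and topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and TOM_ii = 1.
    """
    X, names = _check_expr(expr)
    A = _adjacency(X, beta_power)
    k = A.sum(axis=1)
    # A has zero diagonal, so (A @ A)_ij = sum_u a_iu a_uj already drops u=i,j
    L = A @ A
    kmin = np.minimum.outer(k, k)
    tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return ModuleSet(beta_power=int(beta_power), adjacency=A, tom=tom,
                     connectivity=k, names=names, abs_cor=_abs_cor(X),
                     n_samples=X.shape[0])


def detect_modules(moduleset: ModuleSet, min_module_size: int = 3) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a fixed-height cut scan.

    The cut height is chosen, over the grid of midpoints between consecutive
    merge heights, to maximize the number of clusters meeting the size guard
    (ties toward the lower height). Clusters below the guard are unassigned
    (module 0), as are candidate clusters without cohesion — a module's mean
    within-module |correlation| must exceed five times the null expectation
    sqrt(2 / (pi n)) of an absolute correlation between independent variables,
    which drops the spurious clusters a height scan finds in pure noise.
    Equal cluster counts break toward the cut assigning more biomarkers.
    Surviving modules are numbered by descending size.
    """
    dissim = 1.0 - moduleset.tom
    np.fill_diagonal(dissim, 0.0)
    dissim = 0.5 * (dissim + dissim.T)
    link = average(squareform(dissim, checks=False))
    heights = np.unique(link[:, 2])
    grid = 0.5 * (heights[:-1] + heights[1:]) if heights.size > 1 \
        else np.array([heights[0] / 2 if heights.size else 0.5])
    cor = moduleset.abs_cor
    floor = 5.0 * np.sqrt(2.0 / (np.pi * max(moduleset.n_samples, 2)))

    def cohesive(members) -> bool:
        if len(members) < 2:
            return False
        sub = cor[np.ix_(members, members)]
        within = float(sub[~np.eye(len(members), dtype=bool)].mean())
        return within >= floor

    def qualifying(labels):
        out = []
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) >= min_module_size and cohesive(members):
                out.append((int(c), members))
        return out

    best = None
    for h in grid:
        labels = fcluster(link, t=h, criterion="distance")
        ok = qualifying(labels)
        key = (len(ok), sum(len(m) for _, m in ok))
        if best is None or key > best[0]:
            best = (key, h, labels)
    _, _, labels = best
    keep = qualifying(labels)
    keep.sort(key=lambda item: -len(item[1]))
    remap = {c: i + 1 for i, (c, _) in enumerate(keep)}
    final = np.array([remap.get(int(c), 0) for c in labels])
    module_map = pd.Series(final, index=moduleset.names, name="module")
    moduleset.module_map = module_map
    return module_map


def endotype_module_summary(expr_z, endotypes, module_map: pd.Series) -> pd.DataFrame:
    """Mean Z level per (biomarker, endotype), rows grouped by module.

    The source data of the endotype-by-module heatmap: biomarkers ordered by
    module id (unassigned last), one column per endotype.
    """
    if isinstance(expr_z, pd.DataFrame):
        Z = expr_z
    else:
        Z = pd.DataFrame(np.asarray(expr_z, dtype=float), columns=list(module_map.index))
    labels = np.asarray(getattr(endotypes, "labels", endotypes))
    if len(labels) != len(Z):
        raise ValueError("endotype labels must align with expression rows")
    out = {}
    for e in np.unique(labels):
        members = labels == e
        if not members.any():
            raise ValueError(f"empty endotype {e}")
        out[f"endotype_{e}"] = Z.loc[members, module_map.index].mean()
    summary = pd.DataFrame(out)
    summary["module"] = module_map.reindex(summary.index)
    order = summary["module"].replace(0, summary["module"].max() + 1)
    summary = summary.loc[order.sort_values(kind="mergesort").index]
    return summary
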