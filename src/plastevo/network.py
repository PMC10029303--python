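"""Signed weighted co-expression networks and intramodular connectivity.

Pipeline: MAD filter -> biweight midcorrelation (outlier-capped) -> signed
adjacency a_ij = ((1 + cor)/2)^beta with beta chosen for scale-free fit ->
topological overlap -> average-linkage dendrogram + dynamic tree cut ->
per-gene intramodular connectivity k_IM (sum of within-module adjacencies),
raw and scaled by the per-module maximum.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

# deep-split gap fraction g: a branch is distinct (module) when its gap to the
# attachment height covers >= g of the remaining headroom to the TOM ceiling;
# larger g demands more distinct branches (shallower cutting)
DEEP_SPLIT_SENSITIVITY = {0: 0.5, 1: 0.4, 2: 0.3, 3: 0.2}



def mad_filter(expr: pd.DataFrame) -> pd.Index:
    """Genes with nonzero median absolute deviation across samples.

    Constant and near-constant genes (median deviation zero) produce
    spuriously high correlations and are dropped before network construction.
    """
    dev = np.abs(expr.values - np.median(expr.values, axis=1, keepdims=True))
    mad = np.median(dev, axis=1)
    keep = expr.index[mad > 0]
    if len(keep) == 0:
        raise ValueError("MAD filter removed every gene")
    return keep


def _bicor_weights(x: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, np.ndarray]:
    """Weighted deviations for the biweight midcorrelation, per gene (rows).

    u = (x - med) / (9 MAD), Tukey biweight w = (1 - u^2)^2 on |u| < 1. The
    cap rescales each tail so that at most ``max_p_outliers`` of samples per
    side receive zero weight: if the per-side quantile of u falls beyond
    +/-1, that side's deviations are shrunk so the quantile lands exactly at
    the edge (the side-specific construction used for robust correlation
    with a maximum outlier percentile). Genes with zero MAD fall back to
    Pearson (mean-centred, unit weights).
    """
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(mad > 0, dev / (9.0 * mad), 0.0)
    q_low = np.quantile(u, max_p_outliers, axis=1, keepdims=True)
    q_high = np.quantile(u, 1.0 - max_p_outliers, axis=1, keepdims=True)
    scale_low = np.where(q_low < -1.0, -q_low, 1.0)
    scale_high = np.where(q_high > 1.0, q_high, 1.0)
    u = np.where(u < 0, u / scale_low, u / scale_high)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    weighted = dev * w
    if zero_mad.any():
        warnings.warn("zero-MAD gene(s): falling back to Pearson for their pairs")
        weighted[zero_mad] = x[zero_mad] - x[zero_mad].mean(axis=1, keepdims=True)
    return weighted, zero_mad


def bicor_matrix(expr: pd.DataFrame, max_p_outliers: float = 0.1) -> pd.DataFrame:
    """Gene x gene biweight midcorrelation with side-specific outlier capping."""
    if expr.shape[1] < 5:
        raise ValueError("need at least five samples for a robust correlation")
    weighted, _ = _bicor_weights(expr.values.astype(float), max_p_outliers)
    norms = np.sqrt((weighted**2).sum(axis=1))
    norms[norms == 0] = 1.0
    unit = weighted / norms[:, None]
    cor = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2)^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = np.asarray(cor, dtype=float)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    adjacency = np.asarray(adjacency, dtype=float)
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution fit, plus mean connectivity.

    Connectivities are split into ``n_bins`` equal-occupancy bins; log10
    frequency is regressed on log10 mean connectivity per bin. R^2 is
    reported negative when the slope is positive (anti-scale-free).
    """
    k = connectivity(adjacency)
    if len(k) < 50:
        raise ValueError("need at least 50 genes for a degree-distribution fit")
    return _scale_free_r2(k, n_bins), float(k.mean())


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 density vs log10 mean connectivity over
    equal-occupancy bins (density = bin fraction / bin width)."""
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        warnings.warn("degenerate connectivity distribution; R^2 reported as 0")
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        width = edges[b + 1] - edges[b]
        if mask.sum() == 0 or width <= 0 or k[mask].mean() <= 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean() / width))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.allclose(xs, xs[0]):
        warnings.warn("degenerate connectivity distribution; R^2 reported as 0")
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    return float(-r2 if slope > 0 else r2)


def pick_beta(expr: pd.DataFrame, grid=tuple(range(2, 31, 2)), r2_cut: float = 0.8,
              min_mean_k: float = 30.0, max_p_outliers: float = 0.1
              ) -> tuple[int, pd.DataFrame]:
    """Smallest soft-threshold power with signed scale-free R^2 > ``r2_cut``
    and mean connectivity >= ``min_mean_k``; falls back to the argmax-R^2
    power with a warning when none qualifies. Returns (beta, diagnostics)."""
    grid = sorted(grid)
    if not grid:
        raise ValueError("beta grid must be non-empty")
    cor = bicor_matrix(expr, max_p_outliers=max_p_outliers).values
    rows = []
    for beta in grid:
        r2, mean_k = scale_free_fit(signed_adjacency(cor, beta))
        rows.append({"beta": beta, "scale_free_r2": r2, "mean_connectivity": mean_k})
    diag = pd.DataFrame(rows)
    ok = diag[(diag["scale_free_r2"] > r2_cut) & (diag["mean_connectivity"] >= min_mean_k)]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        beta = int(diag.loc[diag["scale_free_r2"].idxmax(), "beta"])
        warnings.warn(f"no power met R^2 > {r2_cut} with mean connectivity >= "
                      f"{min_mean_k}; returning argmax-R^2 power {beta}")
    return beta, diag


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix:
    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    shared = a_off @ a_off  # sum_u a_iu a_uj, includes u = i or j only via zeros
    k = a_off.sum(axis=1)
    num = shared + a_off  # shared neighbours already exclude i and j (zero diagonal)
    denom = np.minimum.outer(k, k) + 1.0 - a_off
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _subtree_leaves(node: int, left: np.ndarray, right: np.ndarray, n: int) -> list[int]:
    leaves, stack = [], [node]
    while stack:
        v = stack.pop()
        if v < n:
            leaves.append(v)
        else:
            stack.extend((int(left[v - n]), int(right[v - n])))
    return leaves


def detect_modules(tom_dissimilarity: np.ndarray, min_size: int = 30,
                   deep_split: int = 2, height_cap: float = 0.97) -> np.ndarray:
    """Module labels from average-linkage clustering of the TOM dissimilarity
    with an adaptive branch cut (a 'tree'-flavoured dynamic cut).

    A branch of >= ``min_size`` genes is a *module* when it is (a) tight:
    its own merge height h stays below ``height_cap`` (TOM dissimilarity is
    bounded by 1, and branches merging close to the ceiling are noise), and
    (b) distinct: the gap between h and the height at which the branch
    attaches to the rest of the tree covers at least a fraction g of the
    remaining headroom to the ceiling, attach - h >= g * (1 - h), with g
    mapped from ``deep_split``. Distinct sub-branches take precedence over a
    distinct parent, so nested structure is cut at its deepest resolvable
    level; the root attaches at the ceiling, so a single tight network can
    form one module while pure noise stays unassigned. Genes on no such
    branch get label 0; labels are ordered by decreasing module size.
    """
    if deep_split not in DEEP_SPLIT_SENSITIVITY:
        raise ValueError("deep_split must be one of 0, 1, 2, 3")
    g = DEEP_SPLIT_SENSITIVITY[deep_split]
    d = np.asarray(tom_dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    labels = np.zeros(n, dtype=int)
    if min_size > n or n < 2:
        return labels
    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    linkage = average(squareform(dsym, checks=False))
    left, right, heights = linkage[:, 0], linkage[:, 1], linkage[:, 2]
    counts = linkage[:, 3].astype(int)

    def node_count(v: int) -> int:
        return 1 if v < n else int(counts[v - n])

    def distinct(v: int, attach: float) -> bool:
        if v < n or node_count(v) < min_size:
            return False
        h = float(heights[v - n])
        return h <= height_cap and (attach - h) >= g * (1.0 - h)

    # bottom-up pass: modules_in[v] = module nodes strictly inside v,
    # preferring deeper distinct structure over a distinct ancestor
    modules_in: dict[int, list[int]] = {}

    def contribution(child: int, attach: float) -> list[int]:
        inner = modules_in.get(child, [])
        if inner:
            # deeper distinct structure wins over a distinct wrapper, so
            # stragglers accreted above a tight module stay unassigned
            return inner
        return [child] if distinct(child, attach) else inner

    for i in range(n - 1):
        h = float(heights[i])
        modules_in[n + i] = (contribution(int(left[i]), h)
                             + contribution(int(right[i]), h))

    root = 2 * n - 2
    result = modules_in[root]
    if not result and distinct(root, 1.0):
        result = [root]
    module_leaves = sorted((_subtree_leaves(v, left, right, n) for v in result),
                           key=len, reverse=True)
    for i, leaves in enumerate(module_leaves, start=1):
        labels[leaves] = i
    return labels


def intramodular_connectivity(adjacency: np.ndarray, modules: np.ndarray,
                              genes=None) -> pd.DataFrame:
    """k_IM_i = sum of adjacencies from gene i to the other genes of its
    module; scaled k_IM divides by the per-module maximum (so exactly one
    gene per module attains 1). Unassigned genes (module 0) get NaN."""
    a = np.asarray(adjacency, dtype=float)
    modules = np.asarray(modules)
    if len(modules) != a.shape[0]:
        raise ValueError("module labels must cover all genes")
    k_im = np.full(len(modules), np.nan)
    k_scaled = np.full(len(modules), np.nan)
    for m in np.unique(modules):
        if m == 0:
            continue
        idx = np.flatnonzero(modules == m)
        if idx.size == 0:
            continue
        sub = a[np.ix_(idx, idx)]
        k = sub.sum(axis=1) - np.diag(sub)
        k_im[idx] = k
        k_scaled[idx] = k / k.max() if k.max() > 0 else 0.0
    index = genes if genes is not None else pd.RangeIndex(len(modules))
    return pd.DataFrame({"module_id": modules, "k_im": k_im, "k_im_scaled": k_scaled},
                        index=index)
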