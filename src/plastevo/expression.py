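"""Normalization, per-gene contrast estimation, confounder screening,
sample clustering and the continuous plasticity-evolution measure.

The contrast estimator is a normalized negative-binomial group-mean
contrast: median-of-ratios size factors, moment dispersion pooled across
the contrasted groups with a parametric mean trend (alpha(mu) = a/mu + b)
and halfway shrinkage, delta-method standard errors on the log2 scale and
Wald p-values. Group-mean contrasts are linear by construction, so
log2fc(A,B) + log2fc(B,C) = log2fc(A,C) exactly and the plasticity identity
TC = PC + GC holds downstream without approximation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .containers import CountMatrix
from .simulate import duration_bin
from .stats import bh_adjust

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
FILTER_GRID = (0, 1, 2, 5, 10, 20)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-gene reference is the geometric mean across samples; only genes
    expressed (count > 0) in every sample enter the median.
    """
    counts = cm.counts.values.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; supply a pseudo-reference "
            "or filter samples before normalization")
    ref = np.exp(np.log(counts[all_pos]).mean(axis=1))
    factors = np.median(counts[all_pos] / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="size_factor")


def log_transform(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """log2(count / factor + 1) expression matrix (genes x samples).

    A simple variance-reducing surrogate used for sample clustering and the
    co-expression stage only; the contrast statistics never touch it.
    """
    return np.log2(cm.counts / factors.reindex(cm.samples).values + 1.0)


def sample_cluster(expr: pd.DataFrame, n_clusters: int | None = None):
    """Average-linkage clustering of samples on Euclidean distances over genes.

    Returns (linkage matrix, flat labels). Labels are None unless a cut into
    ``n_clusters`` is requested.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least three samples to cluster")
    dist = pdist(expr.values.T, metric="euclidean")
    linkage = average(dist)
    labels = None
    if n_clusters is not None:
        labels = pd.Series(fcluster(linkage, n_clusters, criterion="maxclust"),
                           index=expr.columns, name="cluster")
    return linkage, labels


# ---------------------------------------------------------------------------
# dispersion machinery


def _pooled_moment_dispersion(norm_counts: np.ndarray, group_masks, inv_sf: np.ndarray
                              ) -> np.ndarray:
    """Method-of-moments NB dispersion pooled across groups.

    Within each group, Var(y_s) = mu / sf_s + alpha * mu^2 for normalized
    counts y = k / sf, so alpha is solved from pooled (variance - Poisson part).
    """
    num = np.zeros(norm_counts.shape[0])
    den = np.zeros(norm_counts.shape[0])
    for mask in group_masks:
        n = int(mask.sum())
        if n < 2:
            continue
        y = norm_counts[:, mask]
        mu = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        num += (n - 1) * (s2 - mu * inv_sf[mask].mean())
        den += (n - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _shrink_to_trend(alpha_raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a / mu + b by least squares and shrink each gene's
    raw estimate halfway to the fitted trend."""
    ok = mu > 0
    if ok.sum() < 10:
        return alpha_raw
    design = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(design, alpha_raw[ok], rcond=None)
    a, b = np.maximum(coef, 0.0)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a / np.maximum(mu, 1e-300) + b, b)
    return np.maximum(0.5 * alpha_raw + 0.5 * trend, DISPERSION_FLOOR)


def _cell_stats(norm_counts: np.ndarray, mask: np.ndarray, inv_sf: np.ndarray,
                alpha: np.ndarray, eps: float):
    """Normalized cell mean, its delta-method variance on the log2 scale."""
    n = int(mask.sum())
    mu = norm_counts[:, mask].mean(axis=1)
    var_mean = mu * inv_sf[mask].mean() / n + alpha * mu**2 / n
    var_log2 = var_mean / ((mu + eps) ** 2 * LN2**2)
    return mu, var_log2


def estimate_contrast(cm: CountMatrix, group_a, group_b,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene log2 fold change (A relative to B), SE, Wald p and BH-adjusted p.

    ``group_a``/``group_b`` are lists of sample ids with >= 2 samples each.
    Size factors default to median-of-ratios over the whole matrix, so
    contrasts from the same matrix share one normalization and compose
    linearly. Genes with zero counts in both groups are flagged
    non-estimable (NaN p) and excluded from testing.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    if factors is None:
        factors = size_factors(cm)
    sf = factors.reindex(cm.samples).values
    norm = cm.counts.values / sf[None, :]
    inv_sf = 1.0 / sf
    eps = 0.5 / sps.hmean(sf)

    in_a = np.asarray(cm.samples.isin(group_a))
    in_b = np.asarray(cm.samples.isin(group_b))
    if in_a.sum() != len(group_a) or in_b.sum() != len(group_b):
        raise ValueError("group sample ids not found in the count matrix")

    mu_pool = norm[:, in_a | in_b].mean(axis=1)
    alpha_raw = _pooled_moment_dispersion(norm, [in_a, in_b], inv_sf)
    alpha = _shrink_to_trend(alpha_raw, mu_pool)

    mu_a, var_a = _cell_stats(norm, in_a, inv_sf, alpha, eps)
    mu_b, var_b = _cell_stats(norm, in_b, inv_sf, alpha, eps)
    log2fc = np.log2(mu_a + eps) - np.log2(mu_b + eps)
    se = np.sqrt(var_a + var_b)

    estimable = (mu_a > 0) | (mu_b > 0)
    pvalue = np.full(len(log2fc), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue[estimable] = 2.0 * sps.norm.sf(np.abs(z[estimable]))
    pvalue[estimable] = np.maximum(pvalue[estimable], np.finfo(float).tiny)
    padj = np.full(len(log2fc), np.nan)
    padj[estimable] = bh_adjust(pvalue[estimable])

    return pd.DataFrame({
        "log2fc": log2fc, "se": se, "pvalue": pvalue, "padj": padj,
        "mean_a": mu_a, "mean_b": mu_b, "dispersion": alpha,
        "estimable": estimable,
    }, index=cm.genes)


# ---------------------------------------------------------------------------
# NB cell-mean likelihood (used by the duration screen)


def _nb_cell_loglik_and_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                             n_iter: int = 40):
    """MLE of a common cell mean (on the normalized scale) for NB counts with
    known per-gene dispersion and per-sample size-factor offsets; returns
    (log-likelihood per gene up to y-only constants, fitted mean)."""
    total = y.sum(axis=1)
    zero = total == 0
    t = np.log(np.maximum((y / sf[None, :]).mean(axis=1), 1e-12))
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = sf[None, :] * np.exp(t)[:, None]
        amu = a * mu
        f = (y - (y + 1.0 / a) * amu / (1.0 + amu)).sum(axis=1)
        fp = -((y + 1.0 / a) * amu / (1.0 + amu) ** 2).sum(axis=1)
        step = np.where(fp < 0, f / fp, 0.0)
        t = t - np.clip(step, -5.0, 5.0)
    mu = sf[None, :] * np.exp(t)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y > 0, y * np.log(mu), 0.0) - (y + 1.0 / a) * np.log1p(a * mu)
    ll = ll.sum(axis=1)
    mean = np.exp(t)
    ll[zero] = 0.0
    mean[zero] = 0.0
    return ll, mean


def _stratum_lrt(y: np.ndarray, sf: np.ndarray, bins: np.ndarray, alpha: np.ndarray):
    """LRT statistic of duration-bin cell means vs a single mean, per gene."""
    ll_null, _ = _nb_cell_loglik_and_mean(y, sf, alpha)
    ll_full = np.zeros_like(ll_null)
    occupied = np.unique(bins)
    for b in occupied:
        mask = bins == b
        ll_b, _ = _nb_cell_loglik_and_mean(y[:, mask], sf[mask], alpha)
        ll_full += ll_b
    return 2.0 * (ll_full - ll_null), len(occupied) - 1


def duration_screen(cm: CountMatrix, fdr: float = 0.05,
                    filter_grid=FILTER_GRID,
                    lowland=("L1", "L2")) -> set[str]:
    """Screen out genes whose expression tracks acclimation duration.

    For each of four strata (lowland pooled x {l, h} garden, highland x
    {l, h}), a per-gene NB likelihood-ratio test compares duration-bin cell
    means (>30/>60/>90 d bins) against a single mean, with df = occupied
    bins - 1. Mean-count independent filtering picks, per stratum, the
    threshold from ``filter_grid`` that maximizes BH discoveries at the
    given FDR. Returns the union of genes flagged in any stratum.
    """
    if "acclimation_days" not in cm.design.columns:
        raise ValueError("metadata must include acclimation_days")
    factors = size_factors(cm)
    sf_all = factors.values
    excluded: set[str] = set()
    strata = [(list(lowland), "l"), (list(lowland), "h"), (["H"], "l"), (["H"], "h")]
    for pops, garden in strata:
        samples = cm.samples_where(population=pops, garden=garden)
        if len(samples) < 3:
            warnings.warn(f"stratum {pops} x {garden}: too few samples, skipped")
            continue
        idx = np.asarray(cm.samples.isin(samples))
        days = cm.design.set_index("sample").loc[samples, "acclimation_days"].values
        bins = duration_bin(days)
        if len(np.unique(bins)) < 2:
            warnings.warn(f"stratum {pops} x {garden}: single duration bin, skipped")
            continue
        y = cm.counts.values[:, idx].astype(float)
        sf = sf_all[idx]
        norm = y / sf[None, :]
        masks = [bins == b for b in np.unique(bins)]
        alpha_raw = _pooled_moment_dispersion(norm, masks, 1.0 / sf)
        alpha = _shrink_to_trend(alpha_raw, norm.mean(axis=1))
        lrt, df = _stratum_lrt(y, sf, bins, alpha)
        pvals = sps.chi2.sf(np.maximum(lrt, 0.0), df)
        mean_counts = norm.mean(axis=1)

        best_hits: pd.Index = pd.Index([])
        best_n = -1
        for thr in sorted(filter_grid):
            keep = mean_counts >= thr
            if keep.sum() == 0:
                continue
            padj = bh_adjust(pvals[keep])
            hits = cm.genes[keep][padj < fdr]
            if len(hits) > best_n:
                best_n = len(hits)
                best_hits = hits
        excluded.update(best_hits)
    return excluded


def interaction_magnitude(cm: CountMatrix, lowland=("L1", "L2"),
                          factors: pd.Series | None = None) -> pd.DataFrame:
    """Continuous plasticity-evolution measure: |(L_h - L_l) - (H_h - H_l)|
    per gene on the log2 scale (the population x acclimation-environment
    interaction, i.e. the reaction-norm divergence), with delta-method SE."""
    if factors is None:
        factors = size_factors(cm)
    sf = factors.reindex(cm.samples).values
    norm = cm.counts.values / sf[None, :]
    inv_sf = 1.0 / sf
    eps = 0.5 / sps.hmean(sf)

    cells = {}
    for name, pops, garden in [("L_l", list(lowland), "l"), ("L_h", list(lowland), "h"),
                               ("H_l", ["H"], "l"), ("H_h", ["H"], "h")]:
        samples = cm.samples_where(population=pops, garden=garden)
        if len(samples) < 2:
            raise ValueError(f"cell {name} has fewer than two samples")
        cells[name] = np.asarray(cm.samples.isin(samples))

    mu_pool = norm[:, np.logical_or.reduce(list(cells.values()))].mean(axis=1)
    alpha_raw = _pooled_moment_dispersion(norm, list(cells.values()), inv_sf)
    alpha = _shrink_to_trend(alpha_raw, mu_pool)

    log2m, var = {}, {}
    for name, mask in cells.items():
        mu, v = _cell_stats(norm, mask, inv_sf, alpha, eps)
        log2m[name] = np.log2(mu + eps)
        var[name] = v
    diff = (log2m["L_h"] - log2m["L_l"]) - (log2m["H_h"] - log2m["H_l"])
    se = np.sqrt(var["L_h"] + var["L_l"] + var["H_h"] + var["H_l"])
    return pd.DataFrame({"magnitude": np.abs(diff), "se": se}, index=cm.genes)
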