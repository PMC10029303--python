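"""Inference battery: exact tests, rank tests, post hoc comparisons,
multiple-testing control and annotation-term enrichment.

Two-sided exact tests (binomial, Fisher) use the minimum-likelihood
convention: the p-value sums the probabilities of all outcomes no more
likely than the observed one.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    padj: float | None = None
    effect: dict = field(default_factory=dict)
    groups: tuple = ()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def binomial_two_sided(k: int, n: int, p0: float) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials against p0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    res = sps.binomtest(int(k), int(n), p0, alternative="two-sided")
    return TestResult(statistic=float(k), pvalue=float(res.pvalue),
                      effect={"proportion": k / n, "null": p0})


def _log_table_prob(row1, col_totals, n_total, r1):
    # multivariate hypergeometric: P(x | margins) for the first row
    lp = -math.lgamma(n_total + 1) + math.lgamma(r1 + 1) + math.lgamma(n_total - r1 + 1)
    for x, c in zip(row1, col_totals):
        lp += (math.lgamma(c + 1) - math.lgamma(x + 1) - math.lgamma(c - x + 1))
    return lp


def _fisher_2xc_exact(table: np.ndarray) -> float:
    col_totals = table.sum(axis=0)
    r1 = int(table[0].sum())
    n_total = int(table.sum())
    obs_lp = _log_table_prob(table[0], col_totals, n_total, r1)
    ranges = [range(int(c) + 1) for c in col_totals[:-1]]
    p = 0.0
    last_c = int(col_totals[-1])
    for combo in itertools.product(*ranges):
        rest = r1 - sum(combo)
        if rest < 0 or rest > last_c:
            continue
        lp = _log_table_prob((*combo, rest), col_totals, n_total, r1)
        if lp <= obs_lp + 1e-7:
            p += math.exp(lp)
    return min(p, 1.0)


def _fisher_2xc_montecarlo(table: np.ndarray, n_draws: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    col_totals = table.sum(axis=0).astype(int)
    r1 = int(table[0].sum())
    n_total = int(table.sum())
    obs_lp = _log_table_prob(table[0], col_totals, n_total, r1)
    draws = rng.multivariate_hypergeometric(col_totals, r1, size=n_draws)
    lg = np.vectorize(math.lgamma)
    lps = (-math.lgamma(n_total + 1) + math.lgamma(r1 + 1)
           + math.lgamma(n_total - r1 + 1)
           + (lg(col_totals + 1.0) - lg(draws + 1.0)
              - lg(col_totals - draws + 1.0)).sum(axis=1))
    hits = int((lps <= obs_lp + 1e-7).sum())
    return (hits + 1) / (n_draws + 1)


def fisher_exact(table, max_enumeration: int = 10**7,
                 n_mc: int = 10**5, seed: int = 0) -> tuple[TestResult, list[TestResult]]:
    """Exact 2 x C Fisher test; returns the omnibus result plus BH-adjusted
    post hoc 2 x 2 comparisons between column pairs when C > 2.

    Enumeration is exact while the table space is small enough, otherwise a
    seeded Monte-Carlo p-value is returned.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x C with C >= 2")
    if (table < 0).any():
        raise ValueError("table entries must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1")
        return TestResult(statistic=np.nan, pvalue=1.0), []

    n_cols = table.shape[1]
    if n_cols == 2:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        omnibus = TestResult(statistic=np.nan, pvalue=float(p))
        return omnibus, []

    space = np.prod(np.minimum(table.sum(axis=0), table[0].sum()) + 1.0)
    if space <= max_enumeration:
        p = _fisher_2xc_exact(table)
    else:
        p = _fisher_2xc_montecarlo(table, n_mc, seed)
    omnibus = TestResult(statistic=np.nan, pvalue=float(p))

    posthoc = []
    pairs = list(itertools.combinations(range(n_cols), 2))
    raw = []
    for i, j in pairs:
        _, pij = sps.fisher_exact(table[:, [i, j]], alternative="two-sided")
        raw.append(pij)
    adj = bh_adjust(raw)
    for (i, j), pij, aij in zip(pairs, raw, adj):
        posthoc.append(TestResult(statistic=np.nan, pvalue=float(pij),
                                  padj=float(aij), groups=(i, j)))
    return omnibus, posthoc


def kruskal_wallis_dunn(groups) -> tuple[TestResult, list[TestResult]]:
    """Tie-corrected Kruskal-Wallis omnibus test plus two-sided Dunn post hoc
    z-tests (BH-adjusted) on all group pairs."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # scipy raises on all-identical data; H is 0 by definition
        kw = TestResult(statistic=0.0, pvalue=1.0)
    else:
        h, p = sps.kruskal(*groups)
        kw = TestResult(statistic=float(h), pvalue=float(p))

    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0

    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs, raw = [], []
    for i, j in pairs:
        sigma2 = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        if sigma2 <= 0 or kw.statistic == 0.0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(sigma2)
        zs.append(z)
        raw.append(1.0 if kw.statistic == 0.0 else float(2 * sps.norm.sf(abs(z))))
    adj = bh_adjust(raw)
    posthoc = [TestResult(statistic=z, pvalue=p, padj=float(a), groups=(i, j))
               for (i, j), z, p, a in zip(pairs, zs, raw, adj)]
    return kw, posthoc


def _exact_spearman_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float,
                           alternative: str) -> float:
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    if alternative == "greater":
        return float((rhos >= rho_obs - 1e-12).mean())
    return float((rhos <= rho_obs + 1e-12).mean())


def spearman_one_sided(x, y, alternative: str = "greater") -> TestResult:
    """One-sided Spearman rank correlation test. Exact permutation null when
    n <= 9, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has undefined rank correlation")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= 9:
        p = _exact_spearman_pvalue(rx, ry, rho, alternative)
    else:
        rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t = rho_c * math.sqrt((n - 2) / (1 - rho_c**2))
        p = float(sps.t.sf(t, n - 2)) if alternative == "greater" else float(sps.t.cdf(t, n - 2))
    return TestResult(statistic=rho, pvalue=min(max(p, np.finfo(float).tiny), 1.0),
                      effect={"rho": rho, "n": n})


def term_levels(terms, hierarchy) -> dict[str, int]:
    """Depth of each term as the shortest path from a root (a node that never
    appears as a child) in the child-parent hierarchy. Terms absent from the
    hierarchy share a single flat level (-1)."""
    parents: dict[str, set[str]] = {}
    children: dict[str, set[str]] = {}
    nodes = set()
    for child, parent in hierarchy or []:
        parents.setdefault(child, set()).add(parent)
        children.setdefault(parent, set()).add(child)
        nodes.update((child, parent))
    roots = [t for t in nodes if t not in parents]
    depth = {r: 0 for r in roots}
    queue = deque(roots)
    while queue:
        node = queue.popleft()
        for ch in children.get(node, ()):
            if ch not in depth:
                depth[ch] = depth[node] + 1
                queue.append(ch)
    return {t: depth.get(t, -1) for t in terms}


def term_enrichment(target, background, annotations, hierarchy=None) -> pd.DataFrame:
    """Per-term one-sided (enrichment) hypergeometric tests with BH control
    applied within each hierarchy level.

    target must be a subset of background; terms with no background genes are
    skipped. Returns a table with term, level, counts, pvalue, padj.
    """
    target = set(target)
    background = set(background)
    if not target <= background:
        raise ValueError("target genes must be a subset of the background")
    rows = []
    n_bg = len(background)
    n_t = len(target)
    levels = term_levels(list(annotations), hierarchy)
    for term, genes in annotations.items():
        term_bg = set(genes) & background
        if not term_bg:
            continue
        k = len(term_bg & target)
        big_k = len(term_bg)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=big_k, n=n_t)
        p = float(sps.hypergeom.sf(k - 1, n_bg, big_k, n_t))
        rows.append({"term": term, "level": levels[term], "n_target": k,
                     "n_term": big_k, "n_background": n_bg,
                     "pvalue": min(p, 1.0)})
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["padj"] = np.nan
    for _, idx in result.groupby("level").groups.items():
        result.loc[idx, "padj"] = bh_adjust(result.loc[idx, "pvalue"].values)
    return result.set_index("term").sort_values("pvalue")
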