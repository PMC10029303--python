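"""Adaptation-associated gene selection via pi and delta-pi statistics.

Genes involved in altitudinal adaptation should differ strongly between the
highland population and each lowland population (H vs L1, H vs L2, measured
in the high-altitude garden) but little between the two lowland populations
(L1 vs L2, low-altitude garden). The pi statistic,
pi = |log2 fold change| * -log10(p), combines magnitude and significance;
delta_pi_1 = pi(H vs L1) - pi(L1 vs L2) and delta_pi_2 likewise penalize
non-altitudinal divergence. Genes in the top quantile of both delta-pi
statistics whose two H-vs-L fold changes share a sign are the
altitudinally concordant differentially expressed (ACDE) set.

pi uses raw per-gene p-values: the selection is rank-based, and a uniform
monotone adjustment would not change the top set, so raw values avoid
ambiguity about the adjustment family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import TestResult, binomial_two_sided

NEUTRAL_CONCORDANCE_NULL = 0.67


def pi_value(log2fc, pvalue) -> np.ndarray:
    """pi = |log2fc| * -log10(p); zero when log2fc = 0 or p = 1.

    p = 0 is clamped to the smallest positive float with a warning.
    """
    log2fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    pvalue = np.atleast_1d(np.asarray(pvalue, dtype=float))
    if np.any(pvalue > 1) or np.any(pvalue < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(pvalue == 0):
        warnings.warn("p = 0 clamped to the smallest positive representable value")
        pvalue = np.maximum(pvalue, np.finfo(float).tiny)
    return np.abs(log2fc) * (-np.log10(pvalue))


def acde_select(c_hl1: pd.DataFrame, c_hl2: pd.DataFrame, c_l1l2: pd.DataFrame,
                q: float = 0.05) -> pd.DataFrame:
    """Select ACDE genes from three contrast tables sharing a gene universe.

    Genes at or above the (1 - q) empirical quantile of both delta-pi
    statistics (ties at the threshold included) are 'selected'; among those,
    ``is_acde`` additionally requires the H-vs-L1 and H-vs-L2 fold changes
    to share a sign. Selection counts are stored in ``result.attrs``.
    """
    if not (c_hl1.index.equals(c_hl2.index) and c_hl1.index.equals(c_l1l2.index)):
        raise ValueError("contrasts must share the same gene universe")
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")

    pi_hl1 = pi_value(c_hl1["log2fc"].values, c_hl1["pvalue"].values)
    pi_hl2 = pi_value(c_hl2["log2fc"].values, c_hl2["pvalue"].values)
    pi_l1l2 = pi_value(c_l1l2["log2fc"].values, c_l1l2["pvalue"].values)
    dpi1 = pi_hl1 - pi_l1l2
    dpi2 = pi_hl2 - pi_l1l2

    thr1 = np.quantile(dpi1, 1.0 - q, method="higher")
    thr2 = np.quantile(dpi2, 1.0 - q, method="higher")
    selected = (dpi1 >= thr1) & (dpi2 >= thr2)
    concordant = np.sign(c_hl1["log2fc"].values) == np.sign(c_hl2["log2fc"].values)
    is_acde = selected & concordant

    result = pd.DataFrame({
        "pi_hl1": pi_hl1, "pi_hl2": pi_hl2, "pi_l1l2": pi_l1l2,
        "dpi1": dpi1, "dpi2": dpi2,
        "direction_hl1": np.where(c_hl1["log2fc"].values >= 0, "up", "down"),
        "direction_hl2": np.where(c_hl2["log2fc"].values >= 0, "up", "down"),
        "selected": selected, "is_acde": is_acde,
    }, index=c_hl1.index)
    result.attrs["n_selected"] = int(selected.sum())
    result.attrs["n_concordant"] = int(is_acde.sum())
    result.attrs["thresholds"] = (float(thr1), float(thr2))
    return result


def concordance_test(k_same: int, n_selected: int,
                     p0: float = NEUTRAL_CONCORDANCE_NULL) -> TestResult:
    """Two-sided exact binomial test of the concordant fraction against the
    neutral expectation (2/3 when the three population deviations are iid)."""
    return binomial_two_sided(k_same, n_selected, p0)


def neutral_sign_concordance(n_genes: int = 100_000, seed: int = 0) -> float:
    """Fraction of genes with sign(H - L1) = sign(H - L2) when the three
    per-population expression deviations are iid Gaussians.

    The shared H term correlates the two contrasts at 1/2, giving an
    expected concordant fraction of 2/3 — the provenance of the 0.67 null.
    """
    rng = np.random.default_rng(seed)
    e_h, e_l1, e_l2 = rng.standard_normal((3, n_genes))
    return float((np.sign(e_h - e_l1) == np.sign(e_h - e_l2)).mean())
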