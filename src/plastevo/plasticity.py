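"""Plasticity decomposition (PC / GC / GCb / TC), reinforcing-vs-reversing
classification with a parametric-bootstrap null, and persistence-vs-evolution
classification of plasticity.

PC is the ancestral (lowland) plastic response (garden h vs l), GC the
highland-vs-lowland contrast in the high-altitude garden, GCb the same
population contrast back in the low-altitude garden, and TC = PC + GC the
total change between populations in their native environments. Plasticity is
reinforcing when PC and GC share a sign and reversing when they oppose; the
persistence/evolution call compares GCb against GC through their ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REINFORCING, REVERSING, UNDEFINED = "reinforcing", "reversing", "undefined"
PERSISTING, EVOLVED, UNCLASSIFIED = "persisting", "evolved", "unclassified"

# GCb-to-GC ratio bins, half-open [low, high); ordered from low to high
# degree of plasticity evolution
RATIO_BINS = {
    "binary": [(0.5, 1.5, PERSISTING), (-0.5, 0.5, EVOLVED)],
    "bin3": [(0.75, 1.25, "evo_low"), (0.25, 0.75, "evo_mid"), (-0.25, 0.25, "evo_high")],
    "bin4": [(0.83, 1.17, "evo_1"), (0.50, 0.83, "evo_2"),
             (0.17, 0.50, "evo_3"), (-0.17, 0.17, "evo_4")],
}


def classify_direction(pc, gc) -> np.ndarray:
    """'reinforcing' for same nonzero signs, 'reversing' for opposite nonzero
    signs, 'undefined' when either estimate is exactly zero."""
    pc = np.atleast_1d(np.asarray(pc, dtype=float))
    gc = np.atleast_1d(np.asarray(gc, dtype=float))
    prod = np.sign(pc) * np.sign(gc)
    return np.where(prod > 0, REINFORCING, np.where(prod < 0, REVERSING, UNDEFINED))


def classify_evolution(gcb, gc, scheme: str = "binary") -> np.ndarray:
    """Categorize the GCb-to-GC ratio into the half-open persistence/evolution
    bins of the requested scheme; ratios outside every bin are 'unclassified'.
    GC must be nonzero (callers pre-filter exact zeros)."""
    if scheme not in RATIO_BINS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(RATIO_BINS)}")
    gcb = np.atleast_1d(np.asarray(gcb, dtype=float))
    gc = np.atleast_1d(np.asarray(gc, dtype=float))
    if np.any(gc == 0):
        raise ValueError("GC = 0 leaves the ratio undefined; pre-filter such genes")
    ratio = gcb / gc
    out = np.full(ratio.shape, UNCLASSIFIED, dtype=object)
    for low, high, label in RATIO_BINS[scheme]:
        out[(ratio >= low) & (ratio < high)] = label
    return out.astype(str)


def bootstrap_classify(pc, se_pc, gc, se_gc, n_boot: int = 1000,
                       threshold: int = 950, seed: int = 0) -> pd.DataFrame:
    """Parametric bootstrap support for the direction call, per gene.

    Draws ``n_boot`` independent Gaussian (PC*, GC*) pairs per gene with
    means equal to the estimates and standard deviations equal to their
    standard errors, classifies each pair, and reports the class reached in
    at least ``threshold`` replicates ('none' otherwise). Although the PC
    and GC estimates share lowland samples, the draws are independent — the
    support threshold is what guards against the shared-sampling-error
    artifact of naive sign classification.
    """
    pc = np.atleast_1d(np.asarray(pc, dtype=float))
    gc = np.atleast_1d(np.asarray(gc, dtype=float))
    se_pc = np.atleast_1d(np.asarray(se_pc, dtype=float))
    se_gc = np.atleast_1d(np.asarray(se_gc, dtype=float))
    if np.any(se_pc <= 0) or np.any(se_gc <= 0):
        raise ValueError("standard errors must be positive")
    if not 0 < threshold <= n_boot:
        raise ValueError("threshold must lie in (0, n_boot]")
    rng = np.random.default_rng(seed)
    n = len(pc)
    support_ri = np.zeros(n, dtype=int)
    support_rv = np.zeros(n, dtype=int)
    batch = max(1, int(2e7) // max(n_boot, 1))
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        pc_star = rng.normal(pc[sl, None], se_pc[sl, None], (sl.stop - sl.start, n_boot))
        gc_star = rng.normal(gc[sl, None], se_gc[sl, None], (sl.stop - sl.start, n_boot))
        same = np.sign(pc_star) * np.sign(gc_star) > 0
        support_ri[sl] = same.sum(axis=1)
        support_rv[sl] = n_boot - support_ri[sl]
    supported = np.where(support_ri >= threshold, REINFORCING,
                         np.where(support_rv >= threshold, REVERSING, "none"))
    return pd.DataFrame({
        "support_reinforcing": support_ri,
        "support_reversing": support_rv,
        "supported_class": supported,
    })


def change_table(c_pc: pd.DataFrame, c_gc: pd.DataFrame, c_gcb: pd.DataFrame,
                 n_boot: int = 1000, threshold: int = 950, seed: int = 0
                 ) -> pd.DataFrame:
    """Assemble the per-gene plasticity table from the three contrasts.

    ``c_pc`` is the lowland h-vs-l contrast, ``c_gc`` the H-vs-lowland
    contrast in garden h, ``c_gcb`` the same contrast in garden l (all on the
    same gene universe). TC = PC + GC exactly. Adds the direction class,
    bootstrap support, the GCb/GC ratio and evolution classes under the
    binary, 3-bin and 4-bin schemes (NaN ratio / 'unclassified' when GC = 0).
    """
    if not (c_pc.index.equals(c_gc.index) and c_pc.index.equals(c_gcb.index)):
        raise ValueError("contrasts must share the same gene universe")
    pc, gc, gcb = (c["log2fc"].values for c in (c_pc, c_gc, c_gcb))
    table = pd.DataFrame({
        "pc": pc, "se_pc": c_pc["se"].values,
        "gc": gc, "se_gc": c_gc["se"].values,
        "gcb": gcb, "se_gcb": c_gcb["se"].values,
        "tc": pc + gc,
        "direction": classify_direction(pc, gc),
    }, index=c_pc.index)

    ok = (table["se_pc"].values > 0) & (table["se_gc"].values > 0)
    boot = pd.DataFrame({"support_reinforcing": 0, "support_reversing": 0,
                         "supported_class": "none"}, index=table.index)
    if ok.any():
        sub = bootstrap_classify(pc[ok], table["se_pc"].values[ok],
                                 gc[ok], table["se_gc"].values[ok],
                                 n_boot=n_boot, threshold=threshold, seed=seed)
        boot.loc[table.index[ok], :] = sub.set_index(table.index[ok])
    table = pd.concat([table, boot], axis=1)

    nonzero_gc = gc != 0
    ratio = np.full(len(table), np.nan)
    ratio[nonzero_gc] = gcb[nonzero_gc] / gc[nonzero_gc]
    table["ratio"] = ratio
    for scheme in RATIO_BINS:
        col = np.full(len(table), UNCLASSIFIED, dtype=object)
        if nonzero_gc.any():
            col[nonzero_gc] = classify_evolution(gcb[nonzero_gc], gc[nonzero_gc], scheme)
        name = "evolution_binary" if scheme == "binary" else f"evolution_{scheme}"
        table[name] = col.astype(str)
    return table


def reversing_fraction_null(sd_pc_grid=(0.1, 0.5, 1.0, 2.0, 5.0), sd_tc: float = 1.0,
                            n_genes: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Geometric null for the reversing excess: PC and TC drawn independently
    from zero-mean normals with GC = TC - PC.

    Every gene with |PC| > |TC| necessarily reverses; among |PC| < |TC| genes
    the reversing fraction is exactly 1/2, so the overall fraction is bounded
    below by 1/2 and approaches it as sd_PC -> 0. Returns per-grid-point
    fractions (overall, among |PC| < |TC|, and the |PC| > |TC| share).
    """
    rows = []
    for i, sd_pc in enumerate(sd_pc_grid):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        pc = rng.normal(0.0, sd_pc, n_genes)
        tc = rng.normal(0.0, sd_tc, n_genes)
        gc = tc - pc
        reversing = np.sign(pc) != np.sign(gc)
        smaller = np.abs(pc) < np.abs(tc)
        rows.append({
            "sd_pc": sd_pc,
            "reversing_fraction": reversing.mean(),
            "reversing_fraction_pc_lt_tc": reversing[smaller].mean(),
            "fraction_pc_gt_tc": (~smaller).mean(),
        })
    return pd.DataFrame(rows)
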