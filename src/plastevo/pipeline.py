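"""End-to-end orchestration: load or simulate counts, screen confounded
genes, estimate contrasts, select adaptation-associated genes, classify
plasticity, build the co-expression network and run the association battery.

Every stage draws randomness from its own substream of the global seed, so
toggling one stage never perturbs another's results. All stage outputs are
plain TSV/JSON files plus an in-memory dict of DataFrames.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, acde, io, network, plasticity, stats
from .containers import CountMatrix
from .expression import (duration_screen, estimate_contrast, interaction_magnitude,
                         log_transform, size_factors)
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("plastevo")

_STAGE_KEYS = {"simulate": 10, "bootstrap": 11, "network": 12, "associations": 13}


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage],))
               .generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Paths, stage toggles and tunables for a full run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    annotations_path: str | None = None
    hierarchy_path: str | None = None
    output_dir: str = "results/pipeline"

    run_screen: bool = True
    run_acde: bool = True
    run_plasticity: bool = True
    run_network: bool = True
    run_associations: bool = True

    acde_quantile: float = 0.05
    concordance_null: float = 0.67
    bootstrap_reps: int = 1000
    bootstrap_threshold: int = 950
    evolution_scheme: str = "binary"
    beta_grid: tuple = tuple(range(2, 31, 2))
    min_module_size: int = 30
    deep_split: int = 2
    min_mean_connectivity: float = 30.0
    fdr: float = 0.05
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def validate(self) -> None:
        if not 0 < self.acde_quantile <= 1:
            raise ValueError("acde_quantile must lie in (0, 1]")
        if not 0 < self.concordance_null < 1:
            raise ValueError("concordance_null must lie in (0, 1)")
        if not 0 < self.bootstrap_threshold <= self.bootstrap_reps:
            raise ValueError("bootstrap_threshold must lie in (0, bootstrap_reps]")
        if self.evolution_scheme not in plasticity.RATIO_BINS:
            raise ValueError(f"unknown evolution scheme {self.evolution_scheme!r}")
        if self.deep_split not in network.DEEP_SPLIT_SENSITIVITY:
            raise ValueError("deep_split must be one of 0, 1, 2, 3")
        for path_attr in ("counts_path", "metadata_path", "annotations_path",
                          "hierarchy_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr} = {p} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "beta_grid" in raw:
            raw["beta_grid"] = tuple(raw["beta_grid"])
        return cls(**raw)


def _jsonable(obj):
    """Recursively convert tuple-keyed dicts / tuples for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(asdict(config)), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_counts(config: PipelineConfig):
    if config.counts_path is not None:
        log.info("loading counts from %s", config.counts_path)
        cm = io.read_counts(config.counts_path, config.metadata_path)
        return cm, None
    sim = SimulationConfig(**{"seed": _stage_seed(config.seed, "simulate"),
                              **config.simulation})
    log.info("simulating counts (%d genes, seed %d)", sim.n_genes, sim.seed)
    cm, truth, _ = simulate_dataset(sim)
    return cm, truth


def _acde_condition_tests(plast: pd.DataFrame, acde_mask: np.ndarray,
                          config: PipelineConfig) -> list[dict]:
    """Frequency and magnitude comparisons within the ACDE set."""
    rows = []
    sub = plast.loc[acde_mask]
    direction = sub["direction"].values
    defined = direction != plasticity.UNDEFINED
    n_rv = int((direction[defined] == plasticity.REVERSING).sum())
    n_def = int(defined.sum())
    if n_def > 0:
        res = stats.binomial_two_sided(n_rv, n_def, 0.5)
        rows.append({"test": "reversing_vs_reinforcing_frequency", "statistic": n_rv,
                     "n": n_def, "pvalue": res.pvalue,
                     "effect": n_rv / n_def})
    evo = sub["evolution_binary"].values
    classified = np.isin(evo, [plasticity.PERSISTING, plasticity.EVOLVED])
    n_evolved = int((evo[classified] == plasticity.EVOLVED).sum())
    if classified.sum() > 0:
        res = stats.binomial_two_sided(n_evolved, int(classified.sum()), 0.5)
        rows.append({"test": "evolved_vs_persisting_frequency", "statistic": n_evolved,
                     "n": int(classified.sum()), "pvalue": res.pvalue,
                     "effect": n_evolved / classified.sum()})
    # |PC| by evolution class; direction x evolution contingency
    both = classified & defined
    if both.sum() > 2:
        evolved = evo[both] == plasticity.EVOLVED
        abs_pc = np.abs(sub["pc"].values[both])
        groups = [abs_pc[evolved], abs_pc[~evolved]]
        if all(len(g) > 0 for g in groups):
            kw, _ = stats.kruskal_wallis_dunn(groups)
            rows.append({"test": "abs_pc_by_evolution", "statistic": kw.statistic,
                         "n": int(both.sum()), "pvalue": kw.pvalue,
                         "effect": float(np.median(groups[0]) - np.median(groups[1]))})
        table = np.array([
            [int(((direction[both] == plasticity.REVERSING) & evolved).sum()),
             int(((direction[both] == plasticity.REVERSING) & ~evolved).sum())],
            [int(((direction[both] == plasticity.REINFORCING) & evolved).sum()),
             int(((direction[both] == plasticity.REINFORCING) & ~evolved).sum())],
        ])
        if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            omnibus, _ = stats.fisher_exact(table.T)
            rows.append({"test": "direction_vs_evolution", "statistic": np.nan,
                         "n": int(table.sum()), "pvalue": omnibus.pvalue,
                         "effect": np.nan})
    return rows


def run_pipeline(config: PipelineConfig, counts: CountMatrix | None = None) -> dict:
    """Execute the enabled stages and write a report bundle to output_dir.

    Returns a dict of result tables; a manifest JSON records the package
    version, seed and a configuration hash.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    results: dict = {}
    if counts is None:
        counts, truth = _load_counts(config)
    else:
        truth = None
    if truth is not None:
        io.write_table(truth, out / "truth.tsv")
        results["truth"] = truth
    io.write_counts(counts, out / "counts.tsv", out / "metadata.tsv")
    results["counts"] = counts

    factors = size_factors(counts)
    io.write_table(factors.to_frame(), out / "size_factors.tsv")

    if config.run_screen:
        log.info("stage: duration screen")
        excluded = duration_screen(counts, fdr=config.fdr)
        io.write_table(pd.DataFrame({"gene": sorted(excluded)}), out / "screened_genes.tsv",
                       index=False)
        results["screened_genes"] = excluded
        keep = [g for g in counts.genes if g not in excluded]
        counts = counts.subset_genes(keep)
        log.info("excluded %d duration-confounded genes", len(excluded))

    log.info("stage: contrasts")
    sel = counts.samples_where
    contrasts = {
        "hl1_h": (sel(population="H", garden="h"), sel(population="L1", garden="h")),
        "hl2_h": (sel(population="H", garden="h"), sel(population="L2", garden="h")),
        "l1l2_l": (sel(population="L1", garden="l"), sel(population="L2", garden="l")),
        "pc_pooled": (sel(population=("L1", "L2"), garden="h"),
                      sel(population=("L1", "L2"), garden="l")),
        "gc_pooled": (sel(population="H", garden="h"),
                      sel(population=("L1", "L2"), garden="h")),
        "gcb_pooled": (sel(population="H", garden="l"),
                       sel(population=("L1", "L2"), garden="l")),
    }
    factors = size_factors(counts)
    ctabs = {}
    for name, (a, b) in contrasts.items():
        ctabs[name] = estimate_contrast(counts, a, b, factors=factors)
        io.write_table(ctabs[name], out / f"contrast_{name}.tsv")
    results["contrasts"] = ctabs

    if config.run_acde:
        log.info("stage: ACDE selection")
        acde_table = acde.acde_select(ctabs["hl1_h"], ctabs["hl2_h"], ctabs["l1l2_l"],
                                      q=config.acde_quantile)
        n_sel = acde_table.attrs["n_selected"]
        n_con = acde_table.attrs["n_concordant"]
        conc = acde.concordance_test(n_con, n_sel, config.concordance_null) \
            if n_sel > 0 else None
        io.write_table(acde_table, out / "acde.tsv")
        io.write_json({"n_selected": n_sel, "n_concordant": n_con,
                       "concordance_pvalue": conc.pvalue if conc else None,
                       "null": config.concordance_null}, out / "acde_summary.json")
        results["acde"] = acde_table
        log.info("selected %d genes, %d concordant", n_sel, n_con)

    if config.run_plasticity:
        log.info("stage: plasticity classification")
        plast = plasticity.change_table(
            ctabs["pc_pooled"], ctabs["gc_pooled"], ctabs["gcb_pooled"],
            n_boot=config.bootstrap_reps, threshold=config.bootstrap_threshold,
            seed=_stage_seed(config.seed, "bootstrap"))
        inter = interaction_magnitude(counts, factors=factors)
        plast["evo_continuous"] = inter["magnitude"]
        plast["evo_continuous_se"] = inter["se"]
        io.write_table(plast, out / "plasticity.tsv")
        results["plasticity"] = plast

    if config.run_network:
        log.info("stage: co-expression network")
        lowland_samples = counts.samples_where(population=("L1", "L2"))
        sub = counts.subset_samples(lowland_samples)
        # filter on raw counts: constant-count genes become perfectly
        # correlated after normalization and would form a spurious module
        retained = network.mad_filter(sub.counts)
        sub = sub.subset_genes(retained)
        expr = log_transform(sub, size_factors(sub)).loc[retained]
        beta, diag = network.pick_beta(expr, grid=config.beta_grid,
                                       min_mean_k=config.min_mean_connectivity)
        cor = network.bicor_matrix(expr)
        adj = network.signed_adjacency(cor.values, beta)
        tom = network.tom_similarity(adj)
        labels = network.detect_modules(1.0 - tom, min_size=config.min_module_size,
                                        deep_split=config.deep_split)
        conn = network.intramodular_connectivity(adj, labels, genes=retained)
        io.write_table(conn, out / "modules.tsv")
        io.write_json({"beta": beta, "diagnostics": diag.to_dict("records")},
                      out / "network_diagnostics.json")
        results["network"] = conn
        results["network_beta"] = beta
        log.info("beta = %d, %d modules", beta, int(len(set(labels) - {0})))

    if config.run_associations and config.run_plasticity:
        log.info("stage: association battery")
        plast = results["plasticity"]
        rows = []
        if config.run_acde and "acde" in results:
            acde_mask = results["acde"]["is_acde"].values
            rows += _acde_condition_tests(plast, acde_mask, config)
            rows += _acde_vs_rest_tests(plast, results, acde_mask)
        if "network" in results:
            rows += _network_association_tests(plast, results["network"])
        assoc = pd.DataFrame(rows)
        if len(assoc):
            assoc["padj"] = stats.bh_adjust(assoc["pvalue"].values)
        io.write_table(assoc, out / "associations.tsv", index=False)
        results["associations"] = assoc

    manifest = {"package_version": __version__, "seed": config.seed,
                "config_hash": _config_hash(config), "config": _jsonable(asdict(config)),
                "numpy": np.__version__, "pandas": pd.__version__}
    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results


def _acde_vs_rest_tests(plast: pd.DataFrame, results: dict,
                        acde_mask: np.ndarray) -> list[dict]:
    rows = []
    abs_pc = np.abs(plast["pc"].values)
    groups = [abs_pc[acde_mask], abs_pc[~acde_mask]]
    if all(len(g) > 1 for g in groups):
        kw, _ = stats.kruskal_wallis_dunn(groups)
        rows.append({"test": "abs_pc_acde_vs_rest", "statistic": kw.statistic,
                     "n": len(abs_pc), "pvalue": kw.pvalue,
                     "effect": float(np.median(groups[0]) - np.median(groups[1]))})
    evo = plast["evo_continuous"].values
    groups = [evo[acde_mask], evo[~acde_mask]]
    if all(len(g) > 1 for g in groups):
        kw, _ = stats.kruskal_wallis_dunn(groups)
        rows.append({"test": "evolution_acde_vs_rest", "statistic": kw.statistic,
                     "n": len(evo), "pvalue": kw.pvalue,
                     "effect": float(np.median(groups[0]) - np.median(groups[1]))})
    if "network" in results:
        conn = results["network"].reindex(plast.index)
        k_im = conn["k_im"].values
        ok = ~np.isnan(k_im)
        groups = [k_im[ok & acde_mask], k_im[ok & ~acde_mask]]
        if all(len(g) > 1 for g in groups):
            kw, _ = stats.kruskal_wallis_dunn(groups)
            rows.append({"test": "k_im_acde_vs_rest", "statistic": kw.statistic,
                         "n": int(ok.sum()), "pvalue": kw.pvalue,
                         "effect": float(np.median(groups[0]) - np.median(groups[1]))})
    return rows


def _network_association_tests(plast: pd.DataFrame, conn: pd.DataFrame) -> list[dict]:
    rows = []
    conn = conn.reindex(plast.index)
    evo = plast["evolution_binary"].values
    for col in ("k_im", "k_im_scaled"):
        k = conn[col].values
        ok = ~np.isnan(k)
        g_evo = k[ok & (evo == plasticity.EVOLVED)]
        g_per = k[ok & (evo == plasticity.PERSISTING)]
        if len(g_evo) > 1 and len(g_per) > 1:
            kw, _ = stats.kruskal_wallis_dunn([g_evo, g_per])
            rows.append({"test": f"{col}_by_evolution", "statistic": kw.statistic,
                         "n": len(g_evo) + len(g_per), "pvalue": kw.pvalue,
                         "effect": float(np.median(g_evo) - np.median(g_per))})
    # continuous evolution vs connectivity (expected negative)
    k = conn["k_im"].values
    ok = ~np.isnan(k) & ~np.isnan(plast["evo_continuous"].values)
    if ok.sum() >= 4 and len(np.unique(k[ok])) > 1:
        res = stats.spearman_one_sided(k[ok], plast["evo_continuous"].values[ok],
                                       alternative="less")
        rows.append({"test": "k_im_vs_evolution_continuous", "statistic": res.statistic,
                     "n": int(ok.sum()), "pvalue": res.pvalue, "effect": res.statistic})
    # module size vs evolved fraction
    mod = conn["module_id"].values
    sizes, fracs = [], []
    for m in sorted(set(mod[~np.isnan(mod)]) - {0}):
        in_m = mod == m
        cls = evo[in_m]
        n_cls = np.isin(cls, [plasticity.EVOLVED, plasticity.PERSISTING]).sum()
        if n_cls == 0:
            continue
        sizes.append(int(in_m.sum()))
        fracs.append(float((cls == plasticity.EVOLVED).sum() / n_cls))
    if len(sizes) >= 4 and len(set(sizes)) > 1 and len(set(fracs)) > 1:
        res = stats.spearman_one_sided(sizes, fracs, alternative="less")
        rows.append({"test": "module_size_vs_evolved_fraction", "statistic": res.statistic,
                     "n": len(sizes), "pvalue": res.pvalue, "effect": res.statistic})
    return rows
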