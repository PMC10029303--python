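"""Synthetic reciprocal-transplant count data with known ground truth.

The generator emulates a three-population, two-garden design: two lowland
populations (L1, L2) and one highland population (H), each split between a
low-altitude garden (l) and a high-altitude garden (h). Per-gene ground
truth comprises a plastic response PC (lowland birds, garden h vs l), a
genetic-based change GC (H vs lowland, garden h), its back-transplant
counterpart GCb (H vs lowland, garden l), module co-expression structure
(shared latent factors on the log2 scale), acclimation-duration effects on
binned durations, and negative-binomial sampling noise with per-gene
dispersion (Var = mu + alpha * mu^2).

Expected log2 group-mean offsets by (population, garden):
    lowland/l: 0           lowland/h: PC
    H/l:       GCb         H/h:       PC + GC
so the estimable contrasts recover PC, GC, GCb and TC = PC + GC exactly in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix

DEFAULT_CELLS = {
    ("H", "h"): 10, ("H", "l"): 10,
    ("L1", "h"): 5, ("L1", "l"): 5,
    ("L2", "h"): 5, ("L2", "l"): 5,
}

DURATION_BIN_EDGES = (30, 60, 90)  # bins: (30,60], (60,90], >90 days


def duration_bin(days) -> np.ndarray:
    """Bin index of acclimation duration: 0 for >30-60 d, 1 for >60-90 d, 2 for >90 d."""
    days = np.asarray(days)
    return np.digitize(days, DURATION_BIN_EDGES[1:], right=True)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Effect-size distributions are log-normal on the magnitude of the log2
    fold change (median ~1 log2 unit); these are free parameters of the
    generator, not estimates of any real dataset.
    """

    n_genes: int = 5000
    cells: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    mean_library_size: float = 3e6
    library_size_sigma: float = 0.25          # log-normal sd of size factors
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion_range: tuple = (0.01, 0.5)     # log-uniform NB dispersion alpha
    fraction_effect: float = 0.3              # genes with nonzero PC/GC
    fraction_reversing: float = 0.5           # of effect genes: sign(PC) != sign(GC)
    fraction_evolved: float = 0.5             # of effect genes: GCb ~ 0 instead of GCb = GC
    pc_log_mean: float = 0.0                  # ln-scale location of |PC| (log2 units)
    pc_log_sd: float = 0.5
    gc_log_mean: float = 0.0
    gc_log_sd: float = 0.5
    n_modules: int = 5
    module_size: int = 50
    loading_strength: float = 1.5             # scales per-gene latent loadings
    fraction_duration: float = 0.05           # duration-sensitive genes
    duration_effect: float = 1.0              # log2 change per duration bin
    fraction_constant: float = 0.02           # MAD-zero genes
    acclimation_days_range: tuple = (35, 94)
    peripheral_evolution: bool = False        # tie evolved plasticity to low module loading
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_effect", "fraction_reversing", "fraction_evolved",
                     "fraction_duration", "fraction_constant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0 or self.n_modules < 0 or self.module_size <= 0:
            raise ValueError("counts must be positive")
        if not self.cells:
            raise ValueError("design must define at least one population x garden cell")
        for cell, n in self.cells.items():
            if n <= 0:
                raise ValueError(f"cell {cell} has size {n}; every cell needs >= 1 bird")
            if n < 2:
                raise ValueError(f"cell {cell} has size {n}; contrasts need >= 2 per cell")
        lo, hi = self.acclimation_days_range
        if lo <= 0 or hi < lo:
            raise ValueError("acclimation_days_range must be a positive, ordered pair")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """One record per simulated bird: sample id, population, garden,
    acclimation days, tissue and batch labels."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    rows = []
    i = 0
    for (pop, garden), n in sorted(config.cells.items()):
        for _ in range(n):
            i += 1
            rows.append({
                "sample": f"S{i:03d}_{pop}_{garden}",
                "population": pop,
                "garden": garden,
                "acclimation_days": int(rng.integers(config.acclimation_days_range[0],
                                                     config.acclimation_days_range[1] + 1)),
                "tissue": "liver",
                "batch": "b1",
            })
    return pd.DataFrame(rows)


def generate_truth(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Ground-truth table: per gene baseline, PC/GC/GCb/TC (log2), direction
    and evolution classes, module id and loading, NB dispersion, duration
    slope, constant-gene flag."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    g = config.n_genes
    genes = [f"g{i:05d}" for i in range(g)]

    baseline_raw = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, g)
    # rescale so the expected total per unit size factor matches the library size
    shift = np.log2(config.mean_library_size / np.sum(2.0 ** baseline_raw))
    baseline = baseline_raw + shift

    log_lo, log_hi = np.log(config.dispersion_range[0]), np.log(config.dispersion_range[1])
    dispersion = np.exp(rng.uniform(log_lo, log_hi, g))

    is_constant = rng.random(g) < config.fraction_constant
    is_effect = (rng.random(g) < config.fraction_effect) & ~is_constant
    is_reversing = rng.random(g) < config.fraction_reversing
    is_evolved = rng.random(g) < config.fraction_evolved

    pc = np.zeros(g)
    gc = np.zeros(g)
    pc_sign = rng.choice([-1.0, 1.0], g)
    pc_mag = rng.lognormal(config.pc_log_mean, config.pc_log_sd, g)
    gc_mag = rng.lognormal(config.gc_log_mean, config.gc_log_sd, g)
    pc[is_effect] = (pc_sign * pc_mag)[is_effect]
    gc_sign = np.where(is_reversing, -pc_sign, pc_sign)
    gc[is_effect] = (gc_sign * gc_mag)[is_effect]

    # module membership: first n_modules * module_size non-constant genes
    module_id = np.zeros(g, dtype=int)
    eligible = np.flatnonzero(~is_constant)
    needed = config.n_modules * config.module_size
    members = eligible[:needed]
    for m in range(config.n_modules):
        module_id[members[m * config.module_size:(m + 1) * config.module_size]] = m + 1
    loading = np.zeros(g)
    in_module = module_id > 0
    loading[in_module] = config.loading_strength * rng.uniform(0.3, 1.0, in_module.sum())

    if config.peripheral_evolution:
        # evolved plasticity assigned to the weakest-loading half within each module,
        # persisting to the strongest; used for connectivity-vs-evolution fixtures
        is_evolved = is_evolved.copy()
        for m in range(1, config.n_modules + 1):
            idx = np.flatnonzero((module_id == m) & is_effect)
            if idx.size == 0:
                continue
            order = idx[np.argsort(loading[idx])]
            half = order.size // 2
            is_evolved[order[:half]] = True
            is_evolved[order[half:]] = False

    ratio = np.ones(g)
    evolved_ratio = rng.uniform(-0.3, 0.3, g)
    ratio = np.where(is_evolved, evolved_ratio, 1.0)
    gcb = np.where(is_effect, ratio * gc, 0.0)

    is_duration = (rng.random(g) < config.fraction_duration) & ~is_constant
    duration_slope = np.where(is_duration, config.duration_effect * rng.choice([-1.0, 1.0], g), 0.0)

    direction = np.where(~is_effect, "none",
                         np.where(is_reversing, "reversing", "reinforcing"))
    evolution = np.where(~is_effect, "other",
                         np.where(is_evolved, "evolved", "persisting"))

    return pd.DataFrame({
        "baseline_log2": baseline,
        "pc_true": pc,
        "gc_true": gc,
        "gcb_true": gcb,
        "tc_true": pc + gc,
        "direction_true": direction,
        "evolution_true": evolution,
        "module_id": module_id,
        "loading": loading,
        "dispersion": dispersion,
        "duration_slope": duration_slope,
        "is_constant": is_constant,
    }, index=pd.Index(genes, name="gene"))


def _effect_offset(truth: pd.DataFrame, population: str, garden: str) -> np.ndarray:
    """Expected log2 offset for a (population, garden) cell."""
    if population in ("L1", "L2"):
        return truth["pc_true"].values if garden == "h" else np.zeros(len(truth))
    if garden == "h":
        return (truth["pc_true"] + truth["gc_true"]).values
    return truth["gcb_true"].values


def simulate_counts(truth: pd.DataFrame, design: pd.DataFrame,
                    seed: int = 0, library_size_sigma: float = 0.25) -> CountMatrix:
    """Negative-binomial counts: count ~ NB(mean = s * 2^(baseline + X),
    dispersion alpha), where X composes PC/GC/GCb effects by population and
    garden, module latent factors and duration effects; s is a log-normal
    library-size factor with geometric mean 1. Constant (MAD-zero) genes get
    identical counts in every sample."""
    if design["sample"].duplicated().any():
        raise ValueError("sample ids must be unique")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    g = len(truth)
    s = len(design)
    size_factors = np.exp(rng.normal(0.0, library_size_sigma, s))
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    module_ids = sorted(set(truth["module_id"]) - {0})
    factors = rng.standard_normal((len(module_ids), s)) if module_ids else np.zeros((0, s))

    log2mu = np.tile(truth["baseline_log2"].values[:, None], (1, s))
    bins = duration_bin(design["acclimation_days"].values)
    for j, (_, sample) in enumerate(design.iterrows()):
        log2mu[:, j] += _effect_offset(truth, sample["population"], sample["garden"])
        log2mu[:, j] += truth["duration_slope"].values * bins[j]
        for mi, m in enumerate(module_ids):
            mask = truth["module_id"].values == m
            log2mu[mask, j] += truth["loading"].values[mask] * factors[mi, j]

    mu = size_factors[None, :] * 2.0 ** log2mu
    alpha = truth["dispersion"].values[:, None]
    counts = np.where(
        alpha < 1e-8,
        rng.poisson(mu),
        rng.negative_binomial(np.maximum(1.0 / np.maximum(alpha, 1e-12), 1e-12),
                              np.clip(1.0 / (1.0 + alpha * mu), 1e-12, 1.0)),
    ).astype(np.int64)

    const = truth["is_constant"].values
    counts[const, :] = np.round(2.0 ** truth["baseline_log2"].values[const])[:, None]

    counts_df = pd.DataFrame(counts, index=truth.index, columns=list(design["sample"]))
    return CountMatrix(counts_df, design)


def simulate_dataset(config: SimulationConfig, seed: int | None = None
                     ) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: design, truth and counts under one seed."""
    if seed is not None:
        config = config.with_(seed=seed)
    design = make_design(config)
    truth = generate_truth(config)
    counts = simulate_counts(truth, design, seed=config.seed,
                             library_size_sigma=config.library_size_sigma)
    return counts, truth, design
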