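#!/usr/bin/env python
"""Decompose expression change into PC (lowland plastic response), GC
(population contrast in the high-altitude garden), GCb (the same contrast
back in the low-altitude garden) and TC = PC + GC; classify reinforcing vs
reversing plasticity with 1000-replicate parametric-bootstrap support; and
classify plasticity persistence vs evolution from the GCb-to-GC ratio,
plus the continuous reaction-norm-divergence measure. Writes the
per-gene plasticity table."""

import argparse
from pathlib import Path

import pandas as pd

from plastevo import io
from plastevo.expression import estimate_contrast, interaction_magnitude, size_factors
from plastevo.plasticity import change_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--screen", type=Path,
                        default=Path("results/prefilter/screened_genes.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/plasticity"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--bootstrap-reps", type=int, default=1000)
    parser.add_argument("--bootstrap-threshold", type=int, default=950)
    args = parser.parse_args()

    cm = io.read_counts(args.data / "counts.tsv", args.data / "metadata.tsv")
    if args.screen.exists():
        excluded = set(pd.read_csv(args.screen, sep="\t")["gene"])
        cm = cm.subset_genes([g for g in cm.genes if g not in excluded])

    args.out.mkdir(parents=True, exist_ok=True)
    factors = size_factors(cm)
    sel = cm.samples_where
    lowland = ("L1", "L2")
    pc = estimate_contrast(cm, sel(population=lowland, garden="h"),
                           sel(population=lowland, garden="l"), factors=factors)
    gc = estimate_contrast(cm, sel(population="H", garden="h"),
                           sel(population=lowland, garden="h"), factors=factors)
    gcb = estimate_contrast(cm, sel(population="H", garden="l"),
                            sel(population=lowland, garden="l"), factors=factors)

    table = change_table(pc, gc, gcb, n_boot=args.bootstrap_reps,
                         threshold=args.bootstrap_threshold, seed=args.seed)
    inter = interaction_magnitude(cm, factors=factors)
    table["evo_continuous"] = inter["magnitude"]
    table["evo_continuous_se"] = inter["se"]
    io.write_table(table, args.out / "plasticity.tsv")

    defined = table["direction"] != "undefined"
    print(f"direction calls: "
          f"{(table['direction'] == 'reversing').sum()} reversing, "
          f"{(table['direction'] == 'reinforcing').sum()} reinforcing "
          f"({defined.sum()} defined)")
    supported = table["supported_class"] != "none"
    print(f"bootstrap-supported (>= {args.bootstrap_threshold}/"
          f"{args.bootstrap_reps}): {supported.sum()} genes, of which "
          f"{(table.loc[supported, 'supported_class'] == 'reversing').sum()} reversing")
    for cls in ("persisting", "evolved", "unclassified"):
        print(f"  evolution (binary) {cls}: "
              f"{(table['evolution_binary'] == cls).sum()}")


if __name__ == "__main__":
    main()
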