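#!/usr/bin/env python
"""Identify adaptation-associated (ACDE) genes: estimate the H-vs-L1 and
H-vs-L2 contrasts in the high-altitude garden and the L1-vs-L2 contrast in
the low-altitude garden, combine them into pi / delta-pi statistics, take
the genes in the top quantile of both delta-pi values with concordant
regulation directions, and test the concordant fraction against the 0.67
neutral null. Writes the contrast tables and the ACDE table."""

import argparse
from pathlib import Path

import pandas as pd

from plastevo import io
from plastevo.acde import acde_select, concordance_test
from plastevo.expression import estimate_contrast, size_factors


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--screen", type=Path,
                        default=Path("results/prefilter/screened_genes.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/acde"))
    parser.add_argument("--acde-quantile", type=float, default=0.05)
    parser.add_argument("--concordance-null", type=float, default=0.67)
    args = parser.parse_args()

    cm = io.read_counts(args.data / "counts.tsv", args.data / "metadata.tsv")
    if args.screen.exists():
        excluded = set(pd.read_csv(args.screen, sep="\t")["gene"])
        cm = cm.subset_genes([g for g in cm.genes if g not in excluded])
        print(f"dropped {len(excluded)} duration-confounded genes; "
              f"{len(cm.genes)} remain")

    args.out.mkdir(parents=True, exist_ok=True)
    factors = size_factors(cm)
    sel = cm.samples_where
    contrasts = {
        "hl1_h": (sel(population="H", garden="h"), sel(population="L1", garden="h")),
        "hl2_h": (sel(population="H", garden="h"), sel(population="L2", garden="h")),
        "l1l2_l": (sel(population="L1", garden="l"), sel(population="L2", garden="l")),
    }
    tables = {}
    for name, (a, b) in contrasts.items():
        tables[name] = estimate_contrast(cm, a, b, factors=factors)
        io.write_table(tables[name], args.out / f"contrast_{name}.tsv")

    acde = acde_select(tables["hl1_h"], tables["hl2_h"], tables["l1l2_l"],
                       q=args.acde_quantile)
    io.write_table(acde, args.out / "acde.tsv")
    n_sel, n_con = acde.attrs["n_selected"], acde.attrs["n_concordant"]
    res = concordance_test(n_con, n_sel, args.concordance_null)
    io.write_json({"n_selected": n_sel, "n_concordant": n_con,
                   "concordant_fraction": n_con / n_sel,
                   "null": args.concordance_null,
                   "binomial_pvalue": res.pvalue}, args.out / "summary.json")
    print(f"selected {n_sel} genes in the top {args.acde_quantile:.0%} of both "
          f"delta-pi statistics; {n_con} ({n_con / n_sel:.0%}) share regulation "
          f"direction in the two H-vs-L contrasts")
    print(f"two-sided binomial test vs {args.concordance_null}: "
          f"p = {res.pvalue:.3g}")


if __name__ == "__main__":
    main()
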