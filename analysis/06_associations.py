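#!/usr/bin/env python
"""Association battery linking plasticity, its evolution and network
position: reversing-vs-reinforcing frequencies among ACDE genes, |PC| by
evolution class, direction x evolution contingency, intramodular
connectivity (k_IM) by evolution class and against the continuous
evolution measure, module size vs evolved fraction, and ACDE vs non-ACDE
comparisons. Writes one row per test with BH-adjusted p-values."""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from plastevo import io, stats
from plastevo.pipeline import (_acde_condition_tests, _acde_vs_rest_tests,
                               _network_association_tests)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--acde", type=Path, default=Path("results/acde/acde.tsv"))
    parser.add_argument("--plasticity", type=Path,
                        default=Path("results/plasticity/plasticity.tsv"))
    parser.add_argument("--network", type=Path,
                        default=Path("results/network/modules.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/associations"))
    args = parser.parse_args()

    plast = io.read_table(args.plasticity)
    results = {}
    rows = []
    if args.acde.exists():
        acde = io.read_table(args.acde).reindex(plast.index)
        mask = acde["is_acde"].fillna(False).values.astype(bool)
        results["acde"] = acde
        rows += _acde_condition_tests(plast, mask, None)
    if args.network.exists():
        results["network"] = io.read_table(args.network)
    if "acde" in results and "network" in results:
        rows += _acde_vs_rest_tests(plast, results, mask)
    if "network" in results:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows += _network_association_tests(plast, results["network"])

    assoc = pd.DataFrame(rows)
    if len(assoc):
        assoc["padj"] = stats.bh_adjust(assoc["pvalue"].values)
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_table(assoc, args.out / "associations.tsv", index=False)
    with pd.option_context("display.width", 120):
        print(assoc.to_string(index=False,
                              float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
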