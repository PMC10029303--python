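"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POPULATIONS = ("L1", "L2", "H")
GARDENS = ("l", "h")

DESIGN_COLUMNS = ["sample", "population", "garden", "acclimation_days", "tissue", "batch"]


@dataclass
class CountMatrix:
    """Integer expression counts (genes x samples) with the sample design attached.

    ``counts`` is a DataFrame indexed by gene id with one column per sample id;
    ``design`` carries one row per sample (population, garden, acclimation days,
    tissue, batch). Sample order of the two tables must agree.
    """

    counts: pd.DataFrame
    design: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("counts must be non-negative")
        design = self.design.reset_index(drop=True)
        missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        if list(self.counts.columns) != list(design["sample"]):
            raise ValueError("count matrix columns must match design sample ids (same order)")
        self.design = design

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_where(self, population=None, garden=None) -> list[str]:
        """Sample ids matching a population (str or iterable) and/or garden."""
        mask = pd.Series(True, index=self.design.index)
        if population is not None:
            pops = [population] if isinstance(population, str) else list(population)
            mask &= self.design["population"].isin(pops)
        if garden is not None:
            mask &= self.design["garden"] == garden
        return list(self.design.loc[mask, "sample"])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        design = self.design.set_index("sample").loc[sample_ids].reset_index()
        return CountMatrix(self.counts[sample_ids], design)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.design.copy())
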