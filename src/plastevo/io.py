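"""TSV/JSON round-tripping for all pipeline tables.

Conventions: gene x sample count matrices are TSV with a header row of sample
ids and gene ids in the first column; metadata and result tables are plain
TSV with a header. Annotation sets use the GMT layout (term, description,
genes...), the term hierarchy a two-column child-parent TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CountMatrix


def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.design.to_csv(metadata_path, sep="\t", index=False)


def read_counts(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    design = pd.read_csv(metadata_path, sep="\t")
    return CountMatrix(counts, design)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_gmt(path) -> dict[str, set[str]]:
    """Term -> gene-set mapping from a GMT file (term, description, genes...)."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            annotations[parts[0]] = set(g for g in parts[2:] if g)
    return annotations


def write_gmt(annotations: dict[str, set[str]], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for term, genes in annotations.items():
            desc = (descriptions or {}).get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_hierarchy(path) -> list[tuple[str, str]]:
    """Child-parent pairs from a two-column TSV (header optional)."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            if i == 0 and parts[0].lower() in {"child", "term"}:
                continue
            pairs.append((parts[0], parts[1]))
    return pairs


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
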