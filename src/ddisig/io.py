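"""Text-format readers and writers.

Expression matrices travel as GCT-like TSV: a header row of gene symbols
and a first column of compound ids.  The classic ``#1.2`` two-line GCT
preamble is tolerated on read and never written.  Feature matrices use the
same row-indexed TSV layout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "default_gene_symbols",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_feature_tsv",
    "write_feature_tsv",
]


def default_gene_symbols(n_genes: int = 978) -> list[str]:
    """Placeholder landmark-gene symbols for synthetic data (G0001..)."""
    return [f"G{i + 1:04d}" for i in range(n_genes)]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a compounds x genes expression matrix from GCT-like TSV."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    skip = 2 if first.startswith("#1.2") else 0
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        raise ValueError(f"expression matrix {path} contains missing values")
    return df.astype(np.float64)


def write_expression_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(Path(path), sep="\t", index_label="compound_id")


def read_feature_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(np.float64)


def write_feature_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(Path(path), sep="\t", index_label="compound_id")
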