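"""Plain-text table input/output (tab-separated, reproducible formatting)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_matrix", "read_matrix", "write_table", "read_table"]

_FLOAT_FMT = "%.10g"


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    """Write a gene-by-sample (or pathway-by-sample) matrix as TSV."""
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix; first column is the row identifier."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
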