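"""Readers for expression matrices and group label tables."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import pandas as pd

from .score import ExpressionMatrix


def read_expression(
    path: str | Path,
    scale: Literal["raw_counts", "log_normalized"] = "log_normalized",
) -> ExpressionMatrix:
    """Gene x sample TSV/CSV (genes in rows, first column = symbol) or an MTX
    triplet given as the ``.mtx`` path with sibling ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` name files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        rows = Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
        cols = Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(values=df, scale=scale)


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV/CSV: sample, group."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
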