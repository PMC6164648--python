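"""Readers for p-value files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .histogram import PValueVector

__all__ = ["read_pvalue_file"]


def read_pvalue_file(path: str | Path, column: str | None = None) -> PValueVector:
    """Read p-values from a plain-text or delimited file.

    Without ``column``: one value per line; blank lines and '#' comments are
    ignored.  With ``column``: the file is parsed as CSV (.csv extension) or
    TSV (anything else) and the named column is used.
    """
    path = Path(path)
    if column is not None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if column not in df.columns:
            raise ValueError(
                f"{path}: no column {column!r}; available: {list(df.columns)}"
            )
        return PValueVector(df[column].to_numpy(dtype=float))

    values = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from exc
    if not values:
        raise ValueError(f"{path}: no p-values found")
    return PValueVector(np.asarray(values))
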