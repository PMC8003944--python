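"""Reading and writing univariate count series.

A count series is a single column of nonnegative integers, optionally with a
header, in CSV or TSV form.  Parsing is strict: floats, negatives and
non-numeric entries are rejected rather than coerced, since a silently
truncated count would corrupt every downstream statistic.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["read_count_series", "write_count_series", "as_counts"]


def as_counts(values: Iterable) -> np.ndarray:
    """Validate an iterable as a nonnegative-integer array."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.ndim != 1:
        raise ValueError("count series must be one-dimensional")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        flt = arr.astype(float)
        if not np.all(np.isfinite(flt)) or not np.all(flt == np.floor(flt)):
            raise ValueError("count series must contain only integers")
        arr = flt.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("count series must be nonnegative")
    return arr.astype(np.int64)


def read_count_series(path: str | os.PathLike) -> np.ndarray:
    """Read a single-column CSV/TSV of counts (header optional)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] != 1:
        raise ValueError(f"expected a single column, found {df.shape[1]} in {path}")
    col = df.iloc[:, 0].str.strip()
    if len(col) and not col.iloc[0].lstrip("+-").isdigit():
        col = col.iloc[1:]  # header line
    if col.empty:
        raise ValueError(f"no observations found in {path}")
    bad = [v for v in col if not v.lstrip("+").isdigit()]
    if bad:
        raise ValueError(f"non-integer or negative entries in {path}: {bad[:5]}")
    return as_counts(col.astype(np.int64).to_numpy())


def write_count_series(path: str | os.PathLike, values: Iterable, header: str = "count") -> None:
    """Write counts as a single-column CSV with a header."""
    arr = as_counts(values)
    pd.DataFrame({header: arr}).to_csv(path, index=False)
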