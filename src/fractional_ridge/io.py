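"""Reading and writing delimited numeric matrices.

Matrices are stored as delimited text (tab by default, comma accepted),
rows are data points, with an optional single header line of column names.
Writing uses 17 significant digits so a write/read round-trip preserves
float64 values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import FRRError

__all__ = ["MatrixParseError", "read_matrix", "write_matrix"]


class MatrixParseError(FRRError, ValueError):
    """A matrix file is ragged or contains a non-numeric/non-finite cell."""


def read_matrix(
    path, delimiter: str = "\t", header: bool = False
) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix.

    Returns ``(matrix, column_names)``; names are None when ``header`` is
    False.  Ragged rows and unparseable cells raise :class:`MatrixParseError`
    naming the offending line or cell.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            dtype=str,
            keep_default_na=False,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    names = [str(c) for c in df.columns] if header else None
    values = np.empty(df.shape, dtype=float)
    offset = 2 if header else 1  # 1-based file line of the first data row
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise MatrixParseError(
                f"{path}: non-numeric cell {df.iloc[i, j]!r} at line {i + offset}, "
                f"column {j + 1}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise MatrixParseError(
            f"{path}: non-finite value at line {int(i) + offset}, column {int(j) + 1}"
        )
    return values, names


def write_matrix(matrix: np.ndarray, path, delimiter: str = "\t", names=None) -> None:
    """Write a matrix as delimited text (17 significant digits)."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        if names is not None:
            if len(names) != matrix.shape[1]:
                raise MatrixParseError(
                    f"{len(names)} column names for {matrix.shape[1]} columns"
                )
            fh.write(delimiter.join(str(n) for n in names) + "\n")
        for row in matrix:
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")
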