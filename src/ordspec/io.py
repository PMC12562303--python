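"""Reading and writing single-column series files and symbol exports.

The canonical on-disk format is plain text, one float per line, with an
optional single header line (auto-detected).  A delimited file with several
columns can be read by naming the column of interest.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .symbolizer import SymbolSequence, TimeSeries

__all__ = ["read_series", "write_series", "write_symbols"]


def _parse_float(token: str):
    try:
        value = float(token)
    except ValueError:
        return None
    return value


def read_series(path, column: str | int | None = None,
                delimiter: str | None = None) -> TimeSeries:
    """Parse a series file: one float per line (default), or a delimited
    file with ``column`` selecting a named or 0-based numbered column.

    A single leading non-numeric line is treated as a header.  NaN/inf and
    non-numeric lines raise :class:`InvalidInputError` naming the line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    rows = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise InvalidInputError(f"{path}: file contains no data")

    col_idx = 0
    start = 0
    if delimiter is not None or column is not None:
        sep = delimiter if delimiter is not None else ","
        header_cells = [c.strip() for c in rows[0][1].split(sep)]
        if isinstance(column, str):
            if column not in header_cells:
                raise InvalidInputError(
                    f"{path}: column {column!r} not found in header"
                )
            col_idx = header_cells.index(column)
            start = 1
        else:
            col_idx = int(column) if column is not None else 0
            if _parse_float(header_cells[col_idx]) is None:
                start = 1  # header line
        values = []
        for lineno, text in rows[start:]:
            cells = text.split(sep)
            if col_idx >= len(cells):
                raise InvalidInputError(
                    f"{path}: line {lineno}: missing column {col_idx}"
                )
            v = _parse_float(cells[col_idx])
            if v is None or not np.isfinite(v):
                raise InvalidInputError(
                    f"{path}: line {lineno}: invalid value {cells[col_idx]!r}"
                )
            values.append(v)
    else:
        start = 0
        if _parse_float(rows[0][1]) is None:
            start = 1  # single optional header
        values = []
        for lineno, text in rows[start:]:
            v = _parse_float(text)
            if v is None or not np.isfinite(v):
                raise InvalidInputError(
                    f"{path}: line {lineno}: invalid value {text!r}"
                )
            values.append(v)
    if len(values) < 2:
        raise InvalidInputError(f"{path}: need at least 2 samples")
    return TimeSeries(np.asarray(values))


def write_series(path, series) -> None:
    """Write one float per line at full double precision (round-trip safe)."""
    values = series.values if isinstance(series, TimeSeries) else np.asarray(series)
    with open(path, "w", encoding="utf-8") as fh:
        for v in values:
            fh.write(f"{float(v):.17g}\n")


def write_symbols(path, seq: SymbolSequence) -> None:
    """Export a symbol sequence as single-column integer text."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in seq.codes:
            fh.write(f"{int(c)}\n")
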