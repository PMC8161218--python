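"""CSV schema, validation, and round-trip I/O for barn record tables.

One tabular interchange format: RFC 4180 CSV, UTF-8, period decimal. Units
are fixed by column name (``air_temperature_C``, ``relative_humidity_pct``,
``air_velocity_ms``, optional ``skin_temperature_C``,
``respiration_rate_bpm``, ``core_temperature_C``). Environment columns are
required; physiology columns are optional. Rows failing numeric or bound
checks are rejected individually, with reasons and line numbers collected on
the returned table — schema-level problems (missing required columns) abort
the load outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("etis")

__all__ = ["BarnRecordTable", "SchemaError", "read_table", "write_table",
           "REQUIRED_COLUMNS", "OPTIONAL_COLUMNS"]

REQUIRED_COLUMNS = ["air_temperature_C", "relative_humidity_pct", "air_velocity_ms"]
OPTIONAL_COLUMNS = [
    "record_id",
    "timestamp",
    "skin_temperature_C",
    "respiration_rate_bpm",
    "core_temperature_C",
]

#: Physical bounds per column (inclusive).
COLUMN_BOUNDS = {
    "air_temperature_C": (-20.0, 60.0),
    "relative_humidity_pct": (0.0, 100.0),
    "air_velocity_ms": (0.0, 30.0),
    "skin_temperature_C": (20.0, 45.0),
    "respiration_rate_bpm": (0.0, 400.0),
    "core_temperature_C": (30.0, 45.0),
}


class SchemaError(ValueError):
    """The file cannot be interpreted as a barn record table at all."""


def _to_numeric_exact(column: pd.Series) -> pd.Series:
    """Parse strings with Python's correctly rounded float(), NaN on failure.

    pandas' fast to_numeric parser can be off by one ulp, which would break
    the bit-identical round-trip contract of write_table/read_table.
    """

    def convert(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    return column.map(convert).astype(float)


@dataclass
class BarnRecordTable:
    """Validated records plus per-row rejection diagnostics."""

    frame: pd.DataFrame
    row_errors: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


def read_table(path) -> BarnRecordTable:
    """Read and validate a barn record CSV.

    Missing required columns raise :class:`SchemaError`. Rows with
    non-numeric or out-of-bounds values in validated columns are dropped and
    reported in ``row_errors`` as ``(line_number, reason)`` with 1-based line
    numbers counting the header as line 1.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no header") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    errors: list[tuple[int, str]] = []
    keep = np.ones(len(raw), dtype=bool)
    numeric = {}
    for col in raw.columns:
        if col in ("record_id", "timestamp"):
            continue
        values = _to_numeric_exact(raw[col])
        bad = values.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append((i + 2, f"{col} value {raw[col].iloc[i]!r} is not numeric"))
        keep &= ~bad.to_numpy()
        if col in COLUMN_BOUNDS:
            lo, hi = COLUMN_BOUNDS[col]
            oob = (values < lo) | (values > hi)
            for i in np.flatnonzero(oob.to_numpy()):
                errors.append((i + 2, f"{col} out of [{lo},{hi}]"))
            keep &= ~oob.to_numpy()
        numeric[col] = values
        if col in REQUIRED_COLUMNS:
            blank = raw[col].isna() | (raw[col].str.strip() == "")
            for i in np.flatnonzero(blank.to_numpy()):
                errors.append((i + 2, f"{col} is missing"))
            keep &= ~blank.to_numpy()

    frame = raw.loc[keep].copy()
    for col, values in numeric.items():
        frame[col] = values.loc[keep]
    frame = frame.reset_index(drop=True)
    if errors:
        log.warning("%s: rejected %d row(s) during validation", path, len(errors))
    return BarnRecordTable(frame=frame, row_errors=sorted(errors))


def write_table(table, path, decimals: int | None = None) -> None:
    """Write a barn record table (or bare DataFrame) as CSV.

    With ``decimals=None`` (default) floats are written at full repr
    precision and round-trip bit-identically through :func:`read_table`;
    an integer limits output to that many significant digits. An empty
    table yields a re-readable header-only file.
    """
    frame = table.frame if isinstance(table, BarnRecordTable) else table
    fmt = None if decimals is None else f"%.{decimals}g"
    frame.to_csv(path, index=False, float_format=fmt)
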