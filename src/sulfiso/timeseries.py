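"""Batch-culture time series container and delimited-text I/O.

A :class:`CultureTimeSeries` holds one batch experiment's measured
trajectories — time, optical density, sulfate/sulfide chemistry, per-alcohol
concentrations, and δ³⁴S of the two sulfur pools — as a tidy
:class:`pandas.DataFrame` plus a metadata block.

The on-disk format is UTF-8 CSV with a header row and leading ``#``-prefixed
``key: value`` metadata lines.  Per-mil values are stored to 0.01‰ and
concentrations to 0.01 mM (the measurement resolution); optical density is
stored to 1e-4.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

__all__ = [
    "CultureTimeSeries",
    "TimeSeriesValidationError",
    "read_timeseries",
    "write_timeseries",
    "CORE_COLUMNS",
]

#: canonical measurement columns; donor columns are any further ``*_mM``
CORE_COLUMNS = (
    "time_h",
    "od660",
    "sulfate_mM",
    "sulfide_mM",
    "d34S_sulfate_permil",
    "d34S_sulfide_permil",
)

_CONC_SUFFIX = "_mM"
_DELTA_PREFIX = "d34S_"

# storage precision per design: matches measurement resolution
_DECIMALS = {"time_h": 2, "od660": 4}
_DELTA_DECIMALS = 2
_CONC_DECIMALS = 2


class TimeSeriesValidationError(ValueError):
    """Raised when a culture time series violates its schema invariants."""


@dataclass
class CultureTimeSeries:
    """One batch experiment's measured trajectories.

    Parameters
    ----------
    data:
        Tidy frame with ``time_h`` plus any subset of the core measurement
        columns and per-donor ``<name>_mM`` columns.  Missing values are
        permitted per cell; downstream operations handle them explicitly.
    metadata:
        Free-form provenance block (scenario name, seed, initial sulfate,
        temperature, ...).  Written to / read from the ``#`` header lines.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- schema ------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        problems: list[str] = []
        if "time_h" not in df.columns:
            raise TimeSeriesValidationError("missing required column 'time_h'")
        t = df["time_h"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            problems.append("time_h contains non-finite values")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt == 0):
                rows = np.nonzero(dt == 0)[0] + 1
                problems.append(f"duplicate timepoints at rows {rows.tolist()}")
            elif np.any(dt < 0):
                rows = np.nonzero(dt < 0)[0] + 1
                problems.append(f"non-monotone time at rows {rows.tolist()}")
        for col in df.columns:
            if col == "time_h":
                continue
            if col.endswith(_CONC_SUFFIX) or col == "od660":
                vals = df[col].to_numpy(dtype=float)
                bad = np.nonzero(vals < 0)[0]
                for row in bad:
                    problems.append(f"negative value in {col!r} at row {int(row)}")
            elif not col.startswith(_DELTA_PREFIX):
                warnings.warn(f"unknown column {col!r} kept as-is", stacklevel=3)
        if problems:
            raise TimeSeriesValidationError("; ".join(problems))

    # -- convenience -------------------------------------------------------
    @property
    def donor_columns(self) -> list[str]:
        """Per-alcohol concentration columns (``*_mM`` except sulfur pools)."""
        return [
            c
            for c in self.data.columns
            if c.endswith(_CONC_SUFFIX) and c not in ("sulfate_mM", "sulfide_mM")
        ]

    @property
    def initial_sulfate(self) -> float:
        """Initial sulfate (mM): metadata value, else first measured sulfate."""
        if "initial_sulfate_mM" in self.metadata:
            return float(self.metadata["initial_sulfate_mM"])
        s = self.data["sulfate_mM"].dropna()
        if s.empty:
            raise TimeSeriesValidationError("no sulfate data and no metadata value")
        return float(s.iloc[0])

    def copy(self) -> "CultureTimeSeries":
        return CultureTimeSeries(self.data.copy(), dict(self.metadata))

    def __len__(self) -> int:
        return len(self.data)


def _format_value(col: str, x: float) -> str:
    if pd.isna(x):
        return ""
    if col.startswith(_DELTA_PREFIX):
        return f"{x:.{_DELTA_DECIMALS}f}"
    if col.endswith(_CONC_SUFFIX):
        return f"{x:.{_CONC_DECIMALS}f}"
    return f"{x:.{_DECIMALS.get(col, 6)}f}"


def write_timeseries(series: CultureTimeSeries, path: str | Path) -> None:
    """Write a series as CSV with ``#`` metadata header lines."""
    df = series.data
    buf = io.StringIO()
    for key, value in series.metadata.items():
        buf.write(f"# {key}: {value}\n")
    buf.write(",".join(df.columns) + "\n")
    for _, row in df.iterrows():
        buf.write(",".join(_format_value(c, row[c]) for c in df.columns) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _coerce_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_timeseries(path: str | Path) -> CultureTimeSeries:
    """Read a CSV written by :func:`write_timeseries`.

    Raises :class:`TimeSeriesValidationError` listing every malformed cell
    with its row and column.
    """
    text = Path(path).read_text(encoding="utf-8")
    metadata: dict = {}
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = _coerce_meta(value.strip())
            body_start = i + 1
        else:
            break
    body_lines = [ln for ln in lines[body_start:] if ln.strip()]
    if not body_lines:
        raise TimeSeriesValidationError(f"{path}: no data rows")
    header = [c.strip() for c in body_lines[0].split(",")]
    rows: list[list[float]] = []
    errors: list[str] = []
    for rix, line in enumerate(body_lines[1:]):
        cells = line.split(",")
        if len(cells) != len(header):
            errors.append(f"row {rix}: expected {len(header)} cells, got {len(cells)}")
            continue
        parsed: list[float] = []
        for col, cell in zip(header, cells):
            cell = cell.strip()
            if cell == "":
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                errors.append(f"row {rix}, column {col!r}: unparsable value {cell!r}")
                parsed.append(np.nan)
        rows.append(parsed)
    if errors:
        raise TimeSeriesValidationError(f"{path}: " + "; ".join(errors))
    df = pd.DataFrame(rows, columns=header)
    return CultureTimeSeries(df, metadata)
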