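"""Reading and writing ion traces and fit tables as delimited text."""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .single_peak import InsufficientDataError, IonTrace

__all__ = ["read_trace", "read_traces", "write_trace", "write_fit_table"]


class TraceParseError(ValueError):
    """A malformed row was found while parsing a trace file."""


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    head = [
        line for line in path.read_text().splitlines() if not line.startswith("#")
    ][:5]
    for line in head:
        if "\t" in line:
            return "\t"
        if "," in line:
            return ","
    return "\t"


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _build_trace(times, intensities, source: str) -> IonTrace:
    t = np.asarray(times, dtype=float)
    x = np.asarray(intensities, dtype=float)
    if np.any(x < 0):
        raise TraceParseError(f"{source}: negative intensities are not allowed")
    order = np.argsort(t, kind="stable")
    t, x = t[order], x[order]
    # duplicate timestamps: merge by intensity summation
    uniq, inverse = np.unique(t, return_inverse=True)
    if uniq.size < t.size:
        import warnings

        warnings.warn(f"{source}: duplicate timestamps merged by summation")
        merged = np.zeros(uniq.size)
        np.add.at(merged, inverse, x)
        t, x = uniq, merged
    if t.size < 2:
        raise InsufficientDataError(f"{source}: fewer than 2 data points")
    return IonTrace(t, x)


def read_trace(path, delimiter: str | None = None) -> IonTrace:
    """Read a two-column (time, intensity) delimited text file.

    The delimiter is auto-detected (tab, then comma) unless given; a
    non-numeric first row is treated as a header; comment lines start with
    '#'.  Rows are sorted by time; duplicate timestamps are merged by
    summation with a warning; negative intensities are rejected.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    times, intensities = [], []
    first_row = True
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or (row[0].strip().startswith("#")):
                continue
            cells = [c.strip() for c in row if c.strip() != ""]
            if len(cells) < 2:
                raise TraceParseError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            if first_row:
                first_row = False
                if not (_is_number(cells[0]) and _is_number(cells[1])):
                    continue  # header
            if not (_is_number(cells[0]) and _is_number(cells[1])):
                raise TraceParseError(f"{path}:{lineno}: non-numeric value in {cells[:2]}")
            times.append(float(cells[0]))
            intensities.append(float(cells[1]))
    return _build_trace(times, intensities, str(path))


def read_traces(path, delimiter: str | None = None) -> dict[str, IonTrace]:
    """Read a multi-trace table with columns (trace_id, time, intensity)."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, comment="#")
    if df.shape[1] < 3:
        raise TraceParseError(f"{path}: a multi-trace table needs >= 3 columns")
    id_col, t_col, x_col = df.columns[:3]
    return {
        str(key): _build_trace(sub[t_col].to_numpy(), sub[x_col].to_numpy(), f"{path}[{key}]")
        for key, sub in df.groupby(id_col, sort=False)
    }


def _header(seed=None, extra: dict | None = None) -> str:
    from . import __version__

    meta = {"version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if extra:
        meta.update(extra)
        blob = json.dumps(extra, sort_keys=True, default=str).encode()
        meta["config_hash"] = hashlib.sha256(blob).hexdigest()[:12]
    return "# bigauss " + json.dumps(meta, default=str)


def write_trace(trace: IonTrace, path, delimiter: str = "\t", seed=None) -> None:
    """Write a trace as two-column delimited text with a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed=seed) + "\n")
        fh.write(delimiter.join(["time", "intensity"]) + "\n")
        for t, x in zip(trace.times, trace.intensities):
            fh.write(f"{float(t)!r}{delimiter}{float(x)!r}\n")


def write_fit_table(df: pd.DataFrame, path, delimiter: str = "\t", seed=None, config: dict | None = None) -> None:
    """Write a fit/selection/evaluation table with a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed=seed, extra=config) + "\n")
        df.to_csv(fh, sep=delimiter, index=False)
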