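"""Localization tables, frame stacks, and metric records on disk.

Localization tables are delimited text (comma or tab, sniffed) with a
header row and columns ``x,y[,z][,t][,frame]``.  Coordinate columns are
x/y/z/t in nm (t in caller-chosen units); a ``frame`` column, if
present, is carried as per-point labels rather than a coordinate.
Extra columns are tolerated and ignored.  Frame stacks are multi-page
32-bit-float TIFF with a sidecar ground-truth table.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import format_value
from .pointset import PointSet

__all__ = [
    "read_localizations",
    "write_localizations",
    "write_metrics_record",
    "write_frame_stack",
    "read_frame_stack",
]

_COORD_COLUMNS = ("x", "y", "z", "t")


def read_localizations(path) -> PointSet:
    """Read a localization table into a PointSet.

    Raises ``ValueError`` naming the offending line for ragged or
    non-numeric rows, and for files without x/y columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed table ({e})") from None
    cols = {c.strip().lower(): c for c in df.columns}
    coord_cols = [cols[c] for c in _COORD_COLUMNS if c in cols]
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: need at least 'x' and 'y' columns, got {list(df.columns)}")
    for c in coord_cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value in column '{c}' at line {line}")
        if df[c].isna().any():
            line = int(df[c].isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column '{c}' at line {line}")
    coords = df[coord_cols].to_numpy(dtype=float)
    labels = tuple(df[cols["frame"]]) if "frame" in cols else None
    return PointSet(coords, labels)


def write_localizations(ps: PointSet, path, sep: str = ",") -> None:
    """Write a PointSet as a delimited table (round-trip stable)."""
    path = Path(path)
    header = list(_COORD_COLUMNS[: ps.dim])
    if ps.labels is not None:
        header.append("frame")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(header)
        for i, row in enumerate(ps.coords):
            out = [repr(float(v)) for v in row]
            if ps.labels is not None:
                out.append(ps.labels[i])
            w.writerow(out)


def write_metrics_record(record: dict, path, sep: str = ",") -> None:
    """One-row metric table; undefined values serialize as NA."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(record.keys())
        w.writerow(
            format_value(v) if (v is None or isinstance(v, float)) else v
            for v in record.values()
        )


def write_frame_stack(frames: np.ndarray, path) -> None:
    """Write frames (n, K_y, K_x) as a multi-page 32-bit-float TIFF."""
    import tifffile

    tifffile.imwrite(
        Path(path), np.asarray(frames, dtype=np.float32), photometric="minisblack"
    )


def read_frame_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(Path(path))
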