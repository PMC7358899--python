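"""Delimited-text I/O for positions, point clouds, axon bundles and
connection tables.

Everything is tab-separated text with a header row (comma-separated files
are accepted on read); coordinates are micrometres and cell ids 0-based
integers. Round trips preserve values to full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import RECORD_COLUMNS
from .morphology import AxonBundle, QueryPoints

__all__ = [
    "ParseError",
    "read_positions",
    "write_positions",
    "read_querypoints",
    "write_querypoints",
    "read_bundle",
    "write_bundle",
    "read_connections",
    "write_connections",
]


class ParseError(ValueError):
    """A malformed input table (missing column, bad value, duplicate id)."""


def _read_table(path, required, numeric, allow_nan=()) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path.name}: missing column {col!r}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r} at line {line}"
            )
        if vals.isna().any() and col not in allow_nan:
            line = int(vals.isna().idxmax()) + 2
            raise ParseError(f"{path.name}: empty value in column {col!r} at line {line}")
        df[col] = vals
    return df


def _write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # %.17g guarantees bit-exact float round trips
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_positions(path, ids: np.ndarray, coords: np.ndarray) -> None:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    cols = {"cell_id": np.asarray(ids, dtype=np.int64)}
    for d, ax in enumerate("xyz"[: coords.shape[1]]):
        cols[ax] = coords[:, d]
    _write_table(pd.DataFrame(cols), path)


def read_positions(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a per-population position table; returns (ids, coords)."""
    probe = pd.read_csv(Path(path), sep=None, engine="python", nrows=0)
    axes = [ax for ax in "xyz" if ax in probe.columns]
    if not axes:
        raise ParseError(f"{Path(path).name}: missing coordinate columns x, y[, z]")
    df = _read_table(path, ["cell_id", *axes], axes)
    ids = pd.to_numeric(df["cell_id"], errors="coerce")
    if ids.isna().any():
        line = int(ids.isna().idxmax()) + 2
        raise ParseError(f"{Path(path).name}: bad cell_id at line {line}")
    ids = ids.astype(np.int64)
    if ids.duplicated().any():
        dup = int(ids[ids.duplicated()].iloc[0])
        raise ParseError(f"{Path(path).name}: duplicate cell_id {dup}")
    return ids.to_numpy(), df[axes].to_numpy(dtype=float)


def write_querypoints(path, points: QueryPoints) -> None:
    _write_table(points.to_frame(), path)


def read_querypoints(path) -> QueryPoints:
    axes = ["x", "y", "z"]
    probe = pd.read_csv(Path(path), sep=None, engine="python", nrows=0)
    axes = [ax for ax in axes if ax in probe.columns]
    df = _read_table(
        path,
        ["cell_id", "compartment", "segment_id", *axes, "arc_length"],
        [*axes, "arc_length"],
    )
    return QueryPoints.from_frame(df)


def write_bundle(path, bundle: AxonBundle) -> None:
    _write_table(bundle.to_frame(), path)


def read_bundle(path) -> AxonBundle:
    cols = ["x0", "y0", "z0", "x1", "y1", "z1", "arc_origin", "arc_offset"]
    df = _read_table(path, ["cell_id", "axis", *cols], cols)
    return AxonBundle.from_frame(df)


def write_connections(path, records: pd.DataFrame) -> None:
    _write_table(records[RECORD_COLUMNS], path)


def read_connections(path) -> pd.DataFrame:
    df = _read_table(
        path, RECORD_COLUMNS, RECORD_COLUMNS, allow_nan=("path_length_um",)
    )
    return df.astype(
        {"source_id": np.int64, "target_id": np.int64, "target_segment": np.int64}
    )
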