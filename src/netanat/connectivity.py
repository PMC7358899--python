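"""Candidate-synapse search between point clouds and axon bundles.

Distance-based connectivity follows Peter's rule: a contact is plausible
wherever presynaptic and postsynaptic structures approach each other within
a critical radius. Searches run on a K-d tree (scipy ``cKDTree``) built on
the larger of the two clouds; anisotropic acceptance regions (e.g. granule
cell dendrites reaching four times farther sagittally than mediolaterally)
are handled by scaling both clouds before the search, which turns the
critical ball into a real-space ellipsoid with semi-axes r_c / scale_axis.

For bundles of parallel axons the 2D projection method is used instead of
densely resampling each axon into beads: axons project to single points on
the plane perpendicular to the bundle axis, a 2D ranged search finds
laterally close targets, and a final interval test along the axis keeps
only targets within the axonal stretch. This searches a true cylinder
around each axon rather than a bead chain.

All searches return a :data:`RECORD_COLUMNS` DataFrame sorted by
(source, target, segment); reported distances are real-space Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .morphology import AxonBundle, QueryPoints

__all__ = [
    "SearchSpec",
    "RECORD_COLUMNS",
    "ranged_search",
    "connect_point_to_population",
    "connect_by_projection",
    "cap_connections",
    "chunked_connect",
]

RECORD_COLUMNS = [
    "source_id",
    "target_id",
    "target_segment",
    "distance_um",
    "path_length_um",
    "syn_x",
    "syn_y",
    "syn_z",
]


@dataclass(frozen=True)
class SearchSpec:
    """Parameters of one ranged search.

    ``radius``: critical radius r_c (um), inclusive, applied in the scaled
    frame. ``metric_scale``: per-axis factors applied to both clouds before
    the search (default isotropic). ``tree_side``: which cloud hosts the
    K-d tree; ``auto`` picks the larger one (cheaper), and results are
    identical either way.
    """

    radius: float
    metric_scale: tuple[float, ...] | None = None
    tree_side: str = "auto"

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.metric_scale is not None:
            s = tuple(float(v) for v in self.metric_scale)
            if any(v <= 0 for v in s):
                raise ValueError(f"metric_scale must be positive, got {s}")
            object.__setattr__(self, "metric_scale", s)
        if self.tree_side not in ("auto", "source", "target"):
            raise ValueError("tree_side must be auto|source|target")

    def scale_vector(self, ndim: int) -> np.ndarray:
        if self.metric_scale is None:
            return np.ones(ndim)
        s = np.asarray(self.metric_scale, dtype=float)
        if s.size != ndim:
            raise ValueError(f"metric_scale has {s.size} components for {ndim}-D data")
        return s


def _scaled_pairs(src: np.ndarray, tgt: np.ndarray, radius: float, tree_side: str):
    """Index pairs (i_source, j_target) with scaled distance <= radius."""
    if tree_side == "auto":
        tree_side = "target" if tgt.shape[0] >= src.shape[0] else "source"
    if tree_side == "target":
        tree = cKDTree(tgt)
        lists = tree.query_ball_point(src, radius)
        i = np.repeat(np.arange(src.shape[0]), [len(l) for l in lists])
        j = np.concatenate([np.sort(l) for l in lists]) if len(i) else np.empty(0, int)
    else:
        tree = cKDTree(src)
        lists = tree.query_ball_point(tgt, radius)
        j = np.repeat(np.arange(tgt.shape[0]), [len(l) for l in lists])
        i = np.concatenate([np.sort(l) for l in lists]) if len(j) else np.empty(0, int)
    return np.asarray(i, dtype=np.int64), np.asarray(j, dtype=np.int64)


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    order = ["source_id", "target_id", "target_segment", "distance_um"]
    return df.sort_values(order, kind="mergesort").reset_index(drop=True)


def _empty_records(extra=()) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in [*RECORD_COLUMNS, *extra]}).astype(
        {"source_id": np.int64, "target_id": np.int64, "target_segment": np.int64}
    )


def _ranged(source: QueryPoints, target: QueryPoints, spec: SearchSpec) -> pd.DataFrame:
    if len(source) == 0 or len(target) == 0:
        raise ValueError("both point clouds must be non-empty")
    if source.ndim != target.ndim:
        raise ValueError(
            f"dimensionality mismatch: source {source.ndim}-D, target {target.ndim}-D"
        )
    scale = spec.scale_vector(source.ndim)
    i, j = _scaled_pairs(
        source.coords * scale, target.coords * scale, spec.radius, spec.tree_side
    )
    real = np.linalg.norm(source.coords[i] - target.coords[j], axis=1)
    scaled = np.linalg.norm(
        (source.coords[i] - target.coords[j]) * scale, axis=1
    )
    syn = target.coords[j]
    has_arc = bool(np.any(source.arc_length > 0))
    df = pd.DataFrame({
        "source_id": source.cell_id[i],
        "target_id": target.cell_id[j],
        "target_segment": target.segment_id[j],
        "distance_um": real,
        "path_length_um": source.arc_length[i] if has_arc else np.nan,
        "syn_x": syn[:, 0],
        "syn_y": syn[:, 1],
        "syn_z": syn[:, 2] if source.ndim > 2 else 0.0,
        "_scaled_distance": scaled,
    })
    return _sort_records(df)


def ranged_search(
    source: QueryPoints, target: QueryPoints, spec: SearchSpec
) -> pd.DataFrame:
    """All (source point, target point) pairs whose distance in the
    metric-scaled frame is <= ``spec.radius``.

    The reported ``distance_um`` is Euclidean in real (unscaled)
    coordinates; the synapse coordinate is the target point. The source's
    ``arc_length`` (when it carries one, i.e. a rendered structure) is
    reported as the axonal path length; bare point sources report NaN.
    """
    return _ranged(source, target, spec).drop(columns="_scaled_distance")


def connect_point_to_population(
    source: QueryPoints,
    target: QueryPoints,
    spec: SearchSpec,
    distinct_targets: bool = True,
) -> pd.DataFrame:
    """Connect single-point sources (somata) to a target population,
    keeping at most one record per (source cell, target cell) pair.

    With an anisotropic ``metric_scale`` the acceptance region around each
    source is the real-space ellipsoid with semi-axes radius/scale_axis
    (e.g. granule-cell dendrites reach 4 x 7.85 um sagittally when the
    sagittal coordinate is squeezed by 1/4). When a target cell contributes
    several in-range points, the nearest in scaled distance wins; ties
    break on lowest segment id then lowest synapse x (deterministic).
    """
    rec = _ranged(source, target, spec)
    if distinct_targets and len(rec):
        rec = rec.sort_values(
            ["source_id", "target_id", "_scaled_distance", "target_segment", "syn_x"],
            kind="mergesort",
        ).drop_duplicates(["source_id", "target_id"], keep="first")
    return _sort_records(rec.drop(columns="_scaled_distance"))


def connect_by_projection(
    axons: AxonBundle, target: QueryPoints, radius: float
) -> pd.DataFrame:
    """Find (axon, target point) contacts by the 2D projection method.

    A record is emitted iff (i) the target lies within ``radius`` of the
    axon's line in the projection plane perpendicular to the bundle axis,
    and (ii) the target's coordinate along the axis falls inside the axon's
    [start, end] interval (the back-trace step that rejects laterally close
    points beyond the axon's extent). The synapse sits at the foot of the
    perpendicular on the axon; the axonal path length continues the
    bundle's arc-length convention (distance from the arc origin plus the
    stored offset).
    """
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if len(axons) == 0 or len(target) == 0:
        return _empty_records()
    axis = axons.axis
    plane = [d for d in range(axons.start.shape[1]) if d != axis]
    ax2d = axons.start[:, plane]
    tgt2d = target.coords[:, plane]
    tree = cKDTree(tgt2d)
    lists = tree.query_ball_point(ax2d, radius)
    a = np.repeat(np.arange(len(axons)), [len(l) for l in lists])
    if a.size == 0:
        return _empty_records()
    t = np.concatenate([np.sort(l) for l in lists]).astype(np.int64)

    t_ax = target.coords[t, axis]
    lo = np.minimum(axons.start[a, axis], axons.end[a, axis])
    hi = np.maximum(axons.start[a, axis], axons.end[a, axis])
    inside = (t_ax >= lo) & (t_ax <= hi)
    a, t, t_ax = a[inside], t[inside], t_ax[inside]

    dist = np.linalg.norm(ax2d[a] - tgt2d[t], axis=1)
    syn = axons.start[a].copy()
    syn[:, axis] = t_ax
    path = axons.arc_offset[a] + np.abs(t_ax - axons.arc_origin[a])
    df = pd.DataFrame({
        "source_id": axons.cell_id[a],
        "target_id": target.cell_id[t],
        "target_segment": target.segment_id[t],
        "distance_um": dist,
        "path_length_um": path,
        "syn_x": syn[:, 0],
        "syn_y": syn[:, 1],
        "syn_z": syn[:, 2],
    })
    return _sort_records(df)


def cap_connections(
    records: pd.DataFrame, max_per_pair: int | None, keep: str = "nearest"
) -> pd.DataFrame:
    """Post-processing limit on contacts per (source, target) cell pair.

    Long parallel appositions can produce clusters of adjacent contacts;
    this keeps the ``max_per_pair`` nearest records of each pair (ties
    broken by segment id then synapse x, so the result is independent of
    input order). ``None`` (or infinity) is the identity.
    """
    if keep != "nearest":
        raise ValueError("only keep='nearest' is implemented")
    if max_per_pair is None or max_per_pair == np.inf:
        return _sort_records(records.copy())
    if max_per_pair < 1:
        raise ValueError(f"max_per_pair must be >= 1, got {max_per_pair}")
    out = (
        records.sort_values(
            ["source_id", "target_id", "distance_um", "target_segment", "syn_x"],
            kind="mergesort",
        )
        .groupby(["source_id", "target_id"], sort=False)
        .head(int(max_per_pair))
    )
    return _sort_records(out)


def chunked_connect(
    source: QueryPoints,
    target: QueryPoints,
    spec: SearchSpec,
    n_chunks: int = 1,
) -> pd.DataFrame:
    """Map-and-reduce version of :func:`ranged_search`: the source cloud is
    split into ``n_chunks`` blocks searched independently and the results
    are concatenated. The result set equals the serial one for any
    chunking; chunks may be dispatched to workers by a caller, the
    reference implementation runs them serially.
    """
    if n_chunks < 1:
        raise ValueError(f"n_chunks must be >= 1, got {n_chunks}")
    n_chunks = min(n_chunks, len(source))
    parts = []
    for idx in np.array_split(np.arange(len(source)), n_chunks):
        chunk = QueryPoints(
            coords=source.coords[idx],
            cell_id=source.cell_id[idx],
            compartment=source.compartment[idx],
            segment_id=source.segment_id[idx],
            arc_length=source.arc_length[idx],
        )
        parts.append(ranged_search(chunk, target, spec))
    return _sort_records(pd.concat(parts, ignore_index=True))
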