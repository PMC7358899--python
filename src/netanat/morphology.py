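"""Point-cloud and line-segment representations of dendrites and axons.

Extended cellular structures are represented for connectivity search either
as tagged point clouds (:class:`QueryPoints` — one row per sample point,
annotated with the owning cell, compartment, segment and arc-length) or, for
bundles of mutually parallel axons, as line segments (:class:`AxonBundle`)
handled by the 2D projection connector.

The worked example is the cerebellar granular layer: Golgi cells carry two
apical and two basal straight dendrites sampled at 25 and 12 points each;
granule cells emit an ascending axon (AA) rising vertically to a branch
point in the molecular layer where the parallel fiber (PF) extends in both
mediolateral directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "QueryPoints",
    "GoCMorphSpec",
    "AxonBundle",
    "render_goc_dendrites",
    "render_gc_axon",
    "assign_segments",
]

QUERYPOINT_COLUMNS = ["cell_id", "compartment", "segment_id", "x", "y", "z", "arc_length"]


@dataclass
class QueryPoints:
    """A point cloud in which every point knows its owner.

    Attributes
    ----------
    coords : (N, D) float array, um.
    cell_id : (N,) int array — owning cell.
    compartment : (N,) str array — e.g. ``soma``, ``apical_0``, ``AA``.
    segment_id : (N,) int array — electrical segment within the structure.
    arc_length : (N,) float array, um from the structure origin,
        non-decreasing along each structure's point order.
    """

    coords: np.ndarray
    cell_id: np.ndarray
    compartment: np.ndarray
    segment_id: np.ndarray
    arc_length: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = self.coords.shape[0]
        self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        self.compartment = np.asarray(self.compartment, dtype=object)
        self.segment_id = np.asarray(self.segment_id, dtype=np.int64)
        self.arc_length = np.asarray(self.arc_length, dtype=float)
        for name in ("cell_id", "compartment", "segment_id", "arc_length"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} has wrong length (expected {n})")
        if n and (np.any(self.segment_id < 0) or np.any(self.arc_length < 0)):
            raise ValueError("segment_id and arc_length must be non-negative")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_points(cls, coords, cell_id=None, compartment="soma") -> "QueryPoints":
        """Wrap bare positions (e.g. somata or glomerulus centres)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = coords.shape[0]
        if cell_id is None:
            cell_id = np.arange(n)
        return cls(
            coords=coords,
            cell_id=np.asarray(cell_id),
            compartment=np.full(n, compartment, dtype=object),
            segment_id=np.zeros(n, dtype=np.int64),
            arc_length=np.zeros(n),
        )

    @classmethod
    def concat(cls, parts: list["QueryPoints"]) -> "QueryPoints":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty(3)
        return cls(
            coords=np.concatenate([p.coords for p in parts]),
            cell_id=np.concatenate([p.cell_id for p in parts]),
            compartment=np.concatenate([p.compartment for p in parts]),
            segment_id=np.concatenate([p.segment_id for p in parts]),
            arc_length=np.concatenate([p.arc_length for p in parts]),
        )

    @classmethod
    def empty(cls, ndim: int = 3) -> "QueryPoints":
        return cls(
            coords=np.empty((0, ndim)),
            cell_id=np.empty(0, dtype=np.int64),
            compartment=np.empty(0, dtype=object),
            segment_id=np.empty(0, dtype=np.int64),
            arc_length=np.empty(0),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"cell_id": self.cell_id, "compartment": self.compartment,
                "segment_id": self.segment_id}
        for d, ax in enumerate("xyz"[: self.ndim]):
            cols[ax] = self.coords[:, d]
        cols["arc_length"] = self.arc_length
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "QueryPoints":
        axes = [ax for ax in "xyz" if ax in df.columns]
        return cls(
            coords=df[axes].to_numpy(dtype=float),
            cell_id=df["cell_id"].to_numpy(),
            compartment=df["compartment"].to_numpy(dtype=object),
            segment_id=df["segment_id"].to_numpy(),
            arc_length=df["arc_length"].to_numpy(dtype=float),
        )

    def in_box(self, extents) -> np.ndarray:
        """Flag per point: inside the (un-extended) domain box. Dendrites may
        legitimately protrude; downstream users can filter on this."""
        ext = np.asarray(extents, dtype=float)
        return np.all((self.coords >= 0) & (self.coords <= ext), axis=1)


@dataclass(frozen=True)
class GoCMorphSpec:
    """Golgi-cell dendritic morphology.

    Two apical and two basal straight dendrites per cell, represented by 25
    and 12 uniformly spaced points respectively. Dendrites point into the
    upper (apical) or lower (basal) hemisphere with an azimuthal preference
    for the sagittal direction: the azimuth is drawn uniformly inside a cone
    of ``azimuth_halfwidth_deg`` around +y or -y (chosen with equal
    probability per dendrite), the polar angle uniformly inside the
    configured band (measured from the vertical +z axis).

    The dendrite lengths and angular bands are model inputs, not derived
    quantities; the defaults are placeholder values documented as
    assumptions.
    """

    n_apical: int = 2
    n_basal: int = 2
    points_per_apical: int = 25
    points_per_basal: int = 12
    apical_length: float = 150.0
    basal_length: float = 80.0
    apical_polar_deg: tuple[float, float] = (10.0, 60.0)
    basal_polar_deg: tuple[float, float] = (120.0, 170.0)
    azimuth_halfwidth_deg: float = 45.0

    def __post_init__(self):
        if min(self.points_per_apical, self.points_per_basal) < 1:
            raise ValueError("point counts must be >= 1")
        if min(self.apical_length, self.basal_length) < 0:
            raise ValueError("dendrite lengths must be >= 0")

    @property
    def points_per_cell(self) -> int:
        return (
            self.n_apical * self.points_per_apical
            + self.n_basal * self.points_per_basal
        )


@dataclass
class AxonBundle:
    """Parallel line segments sharing one coordinate axis.

    ``start``/``end`` differ only along ``axis``. ``arc_origin`` is the
    coordinate (along the axis) from which axonal path length is measured
    and ``arc_offset`` the path length already travelled at that origin —
    for an ascending axon the soma (offset 0), for a parallel fiber the
    branch point (offset = branch height), so PF path length = height +
    distance along the fiber.
    """

    cell_id: np.ndarray
    start: np.ndarray
    end: np.ndarray
    axis: int
    arc_origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    arc_offset: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        self.start = np.atleast_2d(np.asarray(self.start, dtype=float))
        self.end = np.atleast_2d(np.asarray(self.end, dtype=float))
        n = self.cell_id.shape[0]
        if self.start.shape != self.end.shape or self.start.shape[0] != n:
            raise ValueError("start/end shapes do not match cell_id")
        if not 0 <= self.axis < self.start.shape[1]:
            raise ValueError(f"axis {self.axis} out of range")
        off = np.delete(self.end - self.start, self.axis, axis=1)
        if n and np.any(off != 0):
            raise ValueError("axons are not parallel to the bundle axis")
        if self.arc_origin is None:
            self.arc_origin = self.start[:, self.axis].copy()
        else:
            self.arc_origin = np.asarray(self.arc_origin, dtype=float)
        if self.arc_offset is None:
            self.arc_offset = np.zeros(n)
        else:
            self.arc_offset = np.asarray(self.arc_offset, dtype=float)

    def __len__(self) -> int:
        return self.cell_id.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_id,
            "axis": np.full(len(self), self.axis),
            "x0": self.start[:, 0], "y0": self.start[:, 1], "z0": self.start[:, 2],
            "x1": self.end[:, 0], "y1": self.end[:, 1], "z1": self.end[:, 2],
            "arc_origin": self.arc_origin,
            "arc_offset": self.arc_offset,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AxonBundle":
        axes = df["axis"].unique()
        if len(axes) > 1:
            raise ValueError("bundle file mixes axis values")
        return cls(
            cell_id=df["cell_id"].to_numpy(),
            start=df[["x0", "y0", "z0"]].to_numpy(dtype=float),
            end=df[["x1", "y1", "z1"]].to_numpy(dtype=float),
            axis=int(axes[0]) if len(axes) else 0,
            arc_origin=df["arc_origin"].to_numpy(dtype=float),
            arc_offset=df["arc_offset"].to_numpy(dtype=float),
        )


def _unit_direction(rng, polar_deg, halfwidth_deg, size):
    """Random unit vectors with polar angle uniform in a band and azimuth in
    a sagittal-preference cone (around +y or -y, equal probability)."""
    theta = np.deg2rad(rng.uniform(*polar_deg, size=size))
    base = rng.integers(0, 2, size=size) * np.pi + np.pi / 2  # +y or -y
    phi = base + np.deg2rad(rng.uniform(-halfwidth_deg, halfwidth_deg, size=size))
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def render_goc_dendrites(
    positions: np.ndarray,
    spec: GoCMorphSpec | None = None,
    seed: int = 0,
    cell_ids: np.ndarray | None = None,
) -> QueryPoints:
    """Render Golgi-cell dendrites as a tagged point cloud.

    Each dendrite is a straight segment from the soma to its tip, sampled at
    uniform arc-length spacing length/(n_points - 1) starting at the soma;
    orientations are drawn per dendrite from the spec's angular
    distributions (apical upward, basal downward). An empty position set
    yields an empty cloud.
    """
    spec = spec or GoCMorphSpec()
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return QueryPoints.empty(3)
    n_cells = positions.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n_cells)
    cell_ids = np.asarray(cell_ids, dtype=np.int64)
    rng = substream(seed, "goc-dendrites")

    parts = []
    kinds = [("apical", spec.n_apical, spec.points_per_apical,
              spec.apical_length, spec.apical_polar_deg),
             ("basal", spec.n_basal, spec.points_per_basal,
              spec.basal_length, spec.basal_polar_deg)]
    for kind, n_dend, n_pts, length, polar in kinds:
        for k in range(n_dend):
            dirs = _unit_direction(rng, polar, spec.azimuth_halfwidth_deg, n_cells)
            if n_pts == 1:
                frac = np.array([1.0])
            else:
                frac = np.arange(n_pts) / (n_pts - 1)
            arc = frac * length
            # (cells, points, 3)
            pts = positions[:, None, :] + dirs[:, None, :] * arc[None, :, None]
            parts.append(QueryPoints(
                coords=pts.reshape(-1, 3),
                cell_id=np.repeat(cell_ids, n_pts),
                compartment=np.full(n_cells * n_pts, f"{kind}_{k}", dtype=object),
                segment_id=np.zeros(n_cells * n_pts, dtype=np.int64),
                arc_length=np.tile(arc, n_cells),
            ))
    return QueryPoints.concat(parts)


def render_gc_axon(
    positions: np.ndarray,
    aa_height,
    pf_half_length: float,
    seed: int = 0,
    cell_ids: np.ndarray | None = None,
) -> tuple[AxonBundle, AxonBundle]:
    """Construct granule-cell axons: the ascending axon (AA) rises
    vertically from the soma by the branch height, where the parallel fiber
    (PF) extends symmetrically along the mediolateral (x) axis.

    ``aa_height`` is a scalar, a per-cell array, or a (low, high) tuple from
    which per-cell heights are drawn uniformly (the molecular-layer depth
    band). Path lengths are measured from the soma: along the AA directly,
    and for the PF as branch height + distance along the fiber.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids, dtype=np.int64)
    if pf_half_length < 0:
        raise ValueError("pf_half_length must be >= 0")
    if isinstance(aa_height, tuple):
        lo, hi = aa_height
        if lo < 0 or hi < lo:
            raise ValueError("invalid branch-height interval")
        h = substream(seed, "gc-axon").uniform(lo, hi, size=n)
    else:
        h = np.broadcast_to(np.asarray(aa_height, dtype=float), (n,)).copy()
        if np.any(h < 0):
            raise ValueError("branch heights must be >= 0")

    branch = positions + np.column_stack([np.zeros(n), np.zeros(n), h])
    aa = AxonBundle(
        cell_id=cell_ids, start=positions.copy(), end=branch.copy(), axis=2,
        arc_origin=positions[:, 2].copy(), arc_offset=np.zeros(n),
    )
    shift = np.column_stack([np.full(n, pf_half_length), np.zeros(n), np.zeros(n)])
    pf = AxonBundle(
        cell_id=cell_ids, start=branch - shift, end=branch + shift, axis=0,
        arc_origin=branch[:, 0].copy(), arc_offset=h,
    )
    return aa, pf


def assign_segments(points: QueryPoints, segment_length=10.0) -> QueryPoints:
    """Assign electrical segment ids along each structure.

    Under the default fixed-length rule, ``segment_id = floor(arc_length /
    segment_length)``, clipped so the structure's tip belongs to the last
    segment (a structure of length L has ceil(L / segment_length) segments).
    ``segment_length`` may instead be a callable mapping the structure
    length (um) to a segment count, mirroring electrotonic rules whose
    constants live outside this package. Structures are the (cell_id,
    compartment) groups. Deterministic: identical inputs give identical ids.
    """
    rule = None
    if callable(segment_length):
        rule = segment_length
    elif not segment_length > 0:
        raise ValueError(f"segment_length must be > 0, got {segment_length}")

    df = pd.DataFrame({
        "cell": points.cell_id,
        "comp": points.compartment,
        "arc": points.arc_length,
    })
    seg = np.zeros(len(points), dtype=np.int64)
    for _, idx in df.groupby(["cell", "comp"], sort=False).groups.items():
        idx = np.asarray(idx)
        arc = points.arc_length[idx]
        length = arc.max()
        if rule is not None:
            n_seg = max(1, int(rule(length)))
        else:
            n_seg = max(1, int(np.ceil(length / segment_length)))
        if length == 0:
            ids = np.zeros(idx.size, dtype=np.int64)
        else:
            width = length / n_seg if rule is not None else segment_length
            ids = np.minimum(np.floor(arc / width).astype(np.int64), n_seg - 1)
        seg[idx] = ids
    return QueryPoints(
        coords=points.coords.copy(),
        cell_id=points.cell_id.copy(),
        compartment=points.compartment.copy(),
        segment_id=seg,
        arc_length=points.arc_length.copy(),
    )
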