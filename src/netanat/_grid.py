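"""Uniform-grid fixed-radius neighbour machinery for the Poisson-disk sampler.

A :class:`PointGrid` bins points into cubic cells whose side equals the
query radius, so an exact "is any point within t" test (t <= cell side)
only ever scans the 3^D neighbouring cells. The numba kernels below keep
the sampler's hot loops (candidate rejection, sequential greedy acceptance
within a round, corner-field coverage pruning) in compiled code; all of
them are exact, deterministic and dimension-generic (the neighbour offsets
are passed in as an array).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "PointGrid",
    "ExclusionField",
    "FieldPack",
    "greedy_accept",
    "voxels_alive",
    "neighbor_offsets",
    "corner_offsets",
    "sample_offsets",
]


def neighbor_offsets(ndim: int) -> np.ndarray:
    """The 3^D offsets {-1, 0, 1}^D used for neighbour-cell scans."""
    grids = np.meshgrid(*([np.array([-1, 0, 1], dtype=np.int64)] * ndim), indexing="ij")
    return np.stack(grids, axis=-1).reshape(-1, ndim)


def corner_offsets(ndim: int) -> np.ndarray:
    grids = np.meshgrid(*([np.array([0, 1], dtype=np.int64)] * ndim), indexing="ij")
    return np.stack(grids, axis=-1).reshape(-1, ndim)


SAMPLE_SPACING = 0.5  # voxel-aliveness sample lattice, in units of the side


def sample_offsets(ndim: int) -> np.ndarray:
    """{0, 1/2, 1}^D sample lattice used by the voxel-aliveness certificate;
    covering radius sqrt(D)/4 of the voxel side."""
    base = np.array([0.0, SAMPLE_SPACING, 1.0])
    grids = np.meshgrid(*([base] * ndim), indexing="ij")
    return np.stack(grids, axis=-1).reshape(-1, ndim)


@njit(cache=False)
def _exists_within(q, pts, order, starts, gshape, cell, t, offs):
    n, D = q.shape
    out = np.zeros(n, dtype=np.uint8)
    t2 = t * t
    for i in range(n):
        found = False
        for o in range(offs.shape[0]):
            flat = 0
            ok = True
            for d in range(D):
                c = int(q[i, d] / cell)
                if c < 0:
                    c = 0
                elif c > gshape[d] - 1:
                    c = gshape[d] - 1
                cc = c + offs[o, d]
                if cc < 0 or cc >= gshape[d]:
                    ok = False
                    break
                flat = flat * gshape[d] + cc
            if not ok:
                continue
            for jj in range(starts[flat], starts[flat + 1]):
                j = order[jj]
                s = 0.0
                for d in range(D):
                    dv = q[i, d] - pts[j, d]
                    s += dv * dv
                if s <= t2:
                    found = True
                    break
            if found:
                break
        out[i] = 1 if found else 0
    return out


@njit(cache=False)
def _voxels_alive(
    ij, side, sample_offs, offs,
    apts, aorder, astarts, agshape, acell, at,
    fpts, forder, fstarts, fgshape, fcell, ft, ftoframe, fpt_off, fstart_off,
):
    """1 per voxel iff some sample node is farther than the (margin-reduced)
    exclusion distance from every constraint point — i.e. the voxel cannot
    be certified free of insertable locations. Early-exits at every level:
    first alive node keeps the voxel, first covering constraint kills a
    node."""
    M, D = ij.shape
    F = fcell.shape[0]
    out = np.zeros(M, dtype=np.uint8)
    x = np.empty(D)
    y = np.empty(D)
    nacc = apts.shape[0]
    at2 = at * at
    for v in range(M):
        alive = False
        for k in range(sample_offs.shape[0]):
            for d in range(D):
                x[d] = (ij[v, d] + sample_offs[k, d]) * side
            dead = False
            if nacc > 0 and at > 0:
                found = False
                for o in range(offs.shape[0]):
                    flat = 0
                    okc = True
                    for d in range(D):
                        c = int(x[d] / acell)
                        if c < 0:
                            c = 0
                        elif c > agshape[d] - 1:
                            c = agshape[d] - 1
                        cc = c + offs[o, d]
                        if cc < 0 or cc >= agshape[d]:
                            okc = False
                            break
                        flat = flat * agshape[d] + cc
                    if not okc:
                        continue
                    for jj in range(astarts[flat], astarts[flat + 1]):
                        j = aorder[jj]
                        s = 0.0
                        for d in range(D):
                            dv = x[d] - apts[j, d]
                            s += dv * dv
                        if s <= at2:
                            found = True
                            break
                    if found:
                        break
                dead = found
            if not dead:
                for f in range(F):
                    t = ft[f]
                    if t <= 0:
                        continue
                    cell = fcell[f]
                    for d in range(D):
                        y[d] = x[d] * ftoframe[f, d]
                    found = False
                    for o in range(offs.shape[0]):
                        flat = 0
                        okc = True
                        for d in range(D):
                            c = int(y[d] / cell)
                            if c < 0:
                                c = 0
                            elif c > fgshape[f, d] - 1:
                                c = fgshape[f, d] - 1
                            cc = c + offs[o, d]
                            if cc < 0 or cc >= fgshape[f, d]:
                                okc = False
                                break
                            flat = flat * fgshape[f, d] + cc
                        if not okc:
                            continue
                        base = fstart_off[f]
                        p0 = fpt_off[f]
                        for jj in range(fstarts[base + flat], fstarts[base + flat + 1]):
                            j = p0 + forder[p0 + jj]
                            s = 0.0
                            for d in range(D):
                                dv = y[d] - fpts[j, d]
                                s += dv * dv
                            if s <= t * t:
                                found = True
                                break
                        if found:
                            break
                    if found:
                        dead = True
                        break
            if not dead:
                alive = True
                break
        out[v] = 1 if alive else 0
    return out


@njit(cache=False)
def _greedy(cand, r, cell, gshape, offs):
    """Sequential greedy acceptance: candidate i is kept iff no earlier kept
    candidate lies within r. Exact and order-deterministic."""
    n, D = cand.shape
    keep = np.zeros(n, dtype=np.uint8)
    ncells = 1
    for d in range(D):
        ncells *= gshape[d]
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    r2 = r * r
    for i in range(n):
        flat0 = 0
        for d in range(D):
            c = int(cand[i, d] / cell)
            if c < 0:
                c = 0
            elif c > gshape[d] - 1:
                c = gshape[d] - 1
            flat0 = flat0 * gshape[d] + c
        conflict = False
        for o in range(offs.shape[0]):
            flat = 0
            ok = True
            for d in range(D):
                c = int(cand[i, d] / cell)
                if c < 0:
                    c = 0
                elif c > gshape[d] - 1:
                    c = gshape[d] - 1
                cc = c + offs[o, d]
                if cc < 0 or cc >= gshape[d]:
                    ok = False
                    break
                flat = flat * gshape[d] + cc
            if not ok:
                continue
            j = head[flat]
            while j != -1:
                s = 0.0
                for d in range(D):
                    dv = cand[i, d] - cand[j, d]
                    s += dv * dv
                if s < r2:
                    conflict = True
                    break
                j = nxt[j]
            if conflict:
                break
        if not conflict:
            keep[i] = 1
            nxt[i] = head[flat0]
            head[flat0] = i
    return keep


class PointGrid:
    """Static uniform grid over a point set; cell side = query radius."""

    def __init__(self, points: np.ndarray, cell: float, extents: np.ndarray):
        self.points = np.ascontiguousarray(points, dtype=np.float64)
        self.cell = float(cell)
        ext = np.asarray(extents, dtype=float)
        self.gshape = np.maximum(1, (ext / self.cell).astype(np.int64) + 1)
        self._offs = neighbor_offsets(ext.size)
        ids = np.clip(
            (self.points / self.cell).astype(np.int64), 0, self.gshape - 1
        )
        flat = np.ravel_multi_index(ids.T, self.gshape)
        self.order = np.argsort(flat, kind="stable")
        counts = np.bincount(flat, minlength=int(np.prod(self.gshape)))
        self.starts = np.concatenate(([0], np.cumsum(counts)))

    def exists_within(self, q: np.ndarray, t: float) -> np.ndarray:
        """Boolean per query: is any grid point within distance t (<= cell)?"""
        if self.points.shape[0] == 0 or q.shape[0] == 0:
            return np.zeros(q.shape[0], dtype=bool)
        if t > self.cell:
            raise ValueError("query distance exceeds grid cell size")
        q = np.ascontiguousarray(q, dtype=np.float64)
        return _exists_within(
            q, self.points, self.order, self.starts, self.gshape, self.cell,
            float(t), self._offs,
        ).astype(bool)



def greedy_accept(cand: np.ndarray, r: float, extents: np.ndarray) -> np.ndarray:
    """Order-respecting greedy mutual exclusion at distance r over candidates
    already cleared against all static point sets."""
    if cand.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    ext = np.asarray(extents, dtype=float)
    gshape = np.maximum(1, (ext / r).astype(np.int64) + 1)
    keep = _greedy(
        np.ascontiguousarray(cand, dtype=np.float64), float(r), float(r),
        gshape, neighbor_offsets(ext.size),
    )
    return keep.astype(bool)


@dataclass
class ExclusionField:
    """A static exclusion constraint (a previously placed population).

    ``to_frame`` maps sampler-frame coordinates to the field's own frame
    (for real-space priors under anisotropic sampling this is 1/scale);
    a location x is forbidden when some field point lies within
    ``threshold`` of x mapped to the field frame.
    """

    grid: PointGrid
    threshold: float
    to_frame: np.ndarray

    def forbids(self, x_sampler: np.ndarray) -> np.ndarray:
        return self.grid.exists_within(x_sampler * self.to_frame, self.threshold)

    def corner_margin(self, side: float) -> float:
        # moving by half a voxel side per axis in the sampler frame moves by
        # at most this distance in the field frame
        return 0.5 * side * float(np.linalg.norm(self.to_frame))


class FieldPack:
    """Prior-population exclusion fields packed into flat arrays so the
    fused voxel-aliveness kernel can iterate over them."""

    def __init__(self, fields: list[ExclusionField], ndim: int):
        self.fields = fields
        n = len(fields)
        if n:
            self.pts = np.concatenate([f.grid.points for f in fields])
            self.pt_off = np.concatenate(
                ([0], np.cumsum([f.grid.points.shape[0] for f in fields]))
            ).astype(np.int64)
            self.order = np.concatenate([f.grid.order for f in fields]).astype(np.int64)
            self.starts = np.concatenate([f.grid.starts for f in fields]).astype(np.int64)
            self.start_off = np.concatenate(
                ([0], np.cumsum([f.grid.starts.size for f in fields]))
            ).astype(np.int64)
            self.gshape = np.stack([f.grid.gshape for f in fields]).astype(np.int64)
            self.cell = np.array([f.grid.cell for f in fields], dtype=float)
            self.thr = np.array([f.threshold for f in fields], dtype=float)
            self.to_frame = np.stack([f.to_frame for f in fields]).astype(np.float64)
            self.margin_factor = np.array(
                [0.5 * np.linalg.norm(f.to_frame) for f in fields]
            )
        else:
            self.pts = np.empty((0, ndim))
            self.pt_off = np.zeros(1, dtype=np.int64)
            self.order = np.empty(0, dtype=np.int64)
            self.starts = np.empty(0, dtype=np.int64)
            self.start_off = np.zeros(1, dtype=np.int64)
            self.gshape = np.empty((0, ndim), dtype=np.int64)
            self.cell = np.empty(0)
            self.thr = np.empty(0)
            self.to_frame = np.empty((0, ndim))
            self.margin_factor = np.empty(0)


def voxels_alive(
    ij: np.ndarray,
    side: float,
    samples: np.ndarray,
    accepted: PointGrid | None,
    r: float,
    pack: FieldPack,
) -> np.ndarray:
    """Boolean per voxel: True unless the voxel is provably devoid of
    insertable locations given the accepted-point field (exclusion r, in the
    sampler frame) and the packed prior fields (their own thresholds and
    frames). Margins follow the 1-Lipschitz sample-certificate bound for the
    {0, 1/2, 1}^D node lattice (covering radius sqrt(D)/4 of the side)."""
    D = ij.shape[1]
    margin_sq = float(np.sqrt(D) * side * SAMPLE_SPACING / 2.0)
    at = r - margin_sq
    if accepted is None:
        apts = np.empty((0, D))
        aorder = np.empty(0, dtype=np.int64)
        astarts = np.zeros(1, dtype=np.int64)
        agshape = np.ones(D, dtype=np.int64)
        acell = 1.0
    else:
        apts, aorder, astarts = accepted.points, accepted.order, accepted.starts
        agshape, acell = accepted.gshape, accepted.cell
    ft = pack.thr - pack.margin_factor * side * SAMPLE_SPACING
    alive = _voxels_alive(
        np.ascontiguousarray(ij, dtype=np.int64), float(side),
        np.ascontiguousarray(samples, dtype=np.float64),
        neighbor_offsets(D),
        apts, np.asarray(aorder, dtype=np.int64), np.asarray(astarts, dtype=np.int64),
        np.asarray(agshape, dtype=np.int64), float(acell), float(at),
        pack.pts, pack.order, pack.starts, pack.gshape, pack.cell,
        ft, pack.to_frame, pack.pt_off, pack.start_off,
    )
    return alive.astype(bool)
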