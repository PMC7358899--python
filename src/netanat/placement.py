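"""Poisson-disk placement of quasi-spherical cellular structures.

The sampler is a voxelized dart-throwing variant of Bridson's algorithm:
the generation box is covered by cubic voxels (side r / divisor, at most one
accepted point per voxel), each round throws one uniform candidate into a
random 20% of the eligible voxels, and candidates are accepted when they
keep the minimal distance r to every previously accepted point and to every
earlier-accepted candidate of the same round. In *maximal* mode, rounds that
add almost no points trigger a subdivision step: eligible voxels are split
into 2^D half-side subvoxels and subvoxels provably inside the union of
exclusion balls are discarded, which concentrates the dart throwing on the
remaining free slivers until the packing saturates (no further point can be
inserted anywhere at distance >= r).

On top of the plain sampler, :func:`place_population` adds soft-sphere
jitter, anisotropic (squeezed-frame) sampling, and exclusion against
previously placed populations; :func:`tune_min_distance` searches for the
minimal distance at which maximal packing reproduces a target density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._grid import (
    ExclusionField,
    FieldPack,
    PointGrid,
    corner_offsets,
    greedy_accept,
    sample_offsets,
    voxels_alive,
)
from ._rng import substream
from .domain import PopulationSpec, SamplerConfig, SpatialDomain, TuningResult

__all__ = [
    "complete_fill_distance",
    "bridson_sample",
    "maximal_sample",
    "apply_softness",
    "place_population",
    "tune_min_distance",
    "trim_and_shift",
    "PlacementReport",
]

log = logging.getLogger(__name__)


def complete_fill_distance(volume: float, n_cell: int, ndim: int = 3) -> float:
    """Sphere (disc) diameter at which ``n_cell`` equal spheres exactly fill
    ``volume``: d_c = (6 V / (pi n))^(1/3) in 3D, (4 V / (pi n))^(1/2) in 2D.

    ``volume`` in um^D gives d_c in um. Used as the analytic anchor of the
    minimal-distance tuning search.
    """
    if not volume > 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    if not n_cell >= 1:
        raise ValueError(f"n_cell must be >= 1, got {n_cell}")
    if ndim == 3:
        return (6.0 * volume / (math.pi * n_cell)) ** (1.0 / 3.0)
    if ndim == 2:
        return (4.0 * volume / (math.pi * n_cell)) ** 0.5
    raise ValueError(f"dimensionality must be 2 or 3, got {ndim}")


class _VoxelSampler:
    """Dart-throwing state machine over a shrinking set of eligible voxels.

    Voxels are tracked as integer lattice coordinates ``ij`` at the current
    subdivision level (voxel lower corner = ij * side); all eligible voxels
    share one side length because subdivision always splits every eligible
    voxel at once.
    """

    def __init__(
        self,
        extents,
        r: float,
        config: SamplerConfig,
        rng: np.random.Generator,
        n_target: int | None = None,
        maximal: bool = False,
        fields: list[ExclusionField] | None = None,
    ):
        self.ext = np.asarray(extents, dtype=float)
        self.D = self.ext.size
        if not r > 0:
            raise ValueError(f"minimal distance must be > 0, got {r}")
        self.r = float(r)
        self.cfg = config
        self.rng = rng
        self.n_target = n_target
        self.maximal = maximal
        self.fields = fields or []
        self._fieldpack = FieldPack(self.fields, self.D)

        self.side0 = self.r / config.divisor(self.D)
        shape = np.maximum(1, np.ceil(self.ext / self.side0)).astype(np.int64)
        self.grid_shape = shape
        self.level = 0
        self.side = self.side0
        self.ij = np.indices(shape).reshape(self.D, -1).T.astype(np.int32)
        self.rej = np.zeros(self.ij.shape[0], dtype=np.int32)
        self._child_offs = corner_offsets(self.D).astype(np.int32)
        self._sample_offs = sample_offsets(self.D)

        self.points: list[np.ndarray] = []
        self.n_points = 0
        self._grid: PointGrid | None = None
        self._grid_size = -1
        self._last_prune_state = (-1, -1)
        self.rounds = 0
        self.subdivisions = 0

    # -- helpers ---------------------------------------------------------

    def _accepted_grid(self) -> PointGrid | None:
        if self.n_points == 0:
            return None
        if self._grid is None or self._grid_size != self.n_points:
            self._grid = PointGrid(np.concatenate(self.points), self.r, self.ext)
            self._grid_size = self.n_points
        return self._grid

    def _voxel_bounds(self, ij):
        lo = ij.astype(float) * self.side
        hi = np.minimum(lo + self.side, self.ext)
        return lo, hi

    def _ancestors(self, ij) -> np.ndarray:
        coarse = (ij >> self.level).astype(np.int64)
        return np.ravel_multi_index(coarse.T, self.grid_shape)

    def _ancestors_of_points(self, pts: np.ndarray) -> np.ndarray:
        ij = np.clip((pts / self.side0).astype(np.int64), 0, self.grid_shape - 1)
        return np.ravel_multi_index(ij.T, self.grid_shape)

    def _remove_ancestors(self, anc_ids: np.ndarray) -> None:
        keep = ~np.isin(self._ancestors(self.ij), anc_ids, kind="table")
        self.ij = self.ij[keep]
        self.rej = self.rej[keep]

    def _forbidden(self, x: np.ndarray) -> np.ndarray:
        bad = np.zeros(x.shape[0], dtype=bool)
        for f in self.fields:
            good = ~bad
            if not np.any(good):
                break
            bad[good] = f.forbids(x[good])
        return bad

    # -- coverage pruning ------------------------------------------------

    def _prune_covered(self) -> None:
        """Drop voxels provably devoid of insertable locations.

        The free-distance field of each constraint is 1-Lipschitz, so a
        corner node certifies every location within half a voxel side of it
        (every location whose nearest corner it is): the corner is *dead*
        for the own-population constraint when some accepted point lies
        within r - sqrt(D)*side/2 of it, and dead for a prior population
        when some prior point lies within threshold minus the corresponding
        field-frame margin. A voxel whose 2^D corners are all dead (each by
        any constraint) contains no insertable location and is removed.
        Never over-prunes.
        """
        M = self.ij.shape[0]
        if M == 0 or (self.n_points == 0 and not self.fields):
            return
        prev_n, prev_level = self._last_prune_state
        if (self.n_points, self.level) == (prev_n, prev_level):
            return  # constraint state unchanged since last prune
        self._last_prune_state = (self.n_points, self.level)
        test = None  # all voxels
        if prev_level == self.level and prev_n >= 0 and self.n_points > prev_n:
            # same resolution: a voxel's aliveness can only have changed if
            # a point accepted since the last pass lies within reach of it
            new_pts = np.concatenate(self.points)[prev_n:]
            reach = self.r + math.sqrt(self.D) * self.side
            near = PointGrid(new_pts, reach, self.ext)
            centers = (self.ij + 0.5) * self.side
            test = np.nonzero(near.exists_within(centers, reach))[0]
            if test.size == 0:
                return
        ij = self.ij if test is None else self.ij[test]
        keep = voxels_alive(
            ij, self.side, self._sample_offs, self._accepted_grid(),
            self.r, self._fieldpack,
        )
        if test is not None:
            mask = np.ones(M, dtype=bool)
            mask[test[~keep]] = False
            keep = mask
        if not np.all(keep):
            self.ij = self.ij[keep]
            self.rej = self.rej[keep]

    def _subdivide(self) -> bool:
        """Split eligible voxels into half-side subvoxels after pruning the
        covered ones. Returns False once the resolution floor is reached."""
        self._prune_covered()
        if self.ij.shape[0] == 0:
            return True
        if self.side / 2.0 < self.cfg.min_side_fraction * self.r:
            return False
        children = (
            (self.ij[:, None, :] * np.int32(2)) + self._child_offs[None, :, :]
        ).reshape(-1, self.D)
        self.level += 1
        self.side /= 2.0
        inside = np.all(children.astype(float) * self.side < self.ext, axis=1)
        self.ij = children[inside]
        self.rej = np.zeros(self.ij.shape[0], dtype=np.int32)
        self._prune_covered()
        self.subdivisions += 1
        return True

    # -- main loop -------------------------------------------------------

    def run(self) -> np.ndarray:
        floor_stall = 0
        bridson_stall = 0
        trigger_hint = self.n_target
        rounds_since_prune = 0
        while self.rounds < self.cfg.max_rounds:
            if self.ij.shape[0] == 0:
                break
            if (
                not self.maximal
                and self.n_target is not None
                and self.n_points >= self.n_target
            ):
                break
            self.rounds += 1

            high = np.nonzero(self.rej < self.cfg.rejection_limit)[0]
            exhausted = high.size == 0
            pool = high if not exhausted else np.arange(self.ij.shape[0])
            k = max(1, int(round(self.cfg.candidate_fraction * pool.size)))
            sel = (
                self.rng.permutation(pool)
                if k >= pool.size
                else self.rng.choice(pool, size=k, replace=False)
            )
            lo, hi = self._voxel_bounds(self.ij[sel])
            cand = lo + self.rng.random((sel.size, self.D)) * (hi - lo)

            ok = np.ones(sel.size, dtype=bool)
            grid = self._accepted_grid()
            if grid is not None:
                ok &= ~grid.exists_within(cand, self.r)
            if self.fields and np.any(ok):
                ok[ok] &= ~self._forbidden(cand[ok])

            survivors = np.nonzero(ok)[0]
            kept_local = np.nonzero(greedy_accept(cand[survivors], self.r, self.ext))[0]
            kept = survivors[kept_local]
            if (
                not self.maximal
                and self.n_target is not None
                and self.n_points + kept.size > self.n_target
            ):
                kept = kept[: self.n_target - self.n_points]

            n_new = kept.size
            accepted_mask = np.zeros(sel.size, dtype=bool)
            accepted_mask[kept] = True
            rejected_vox = sel[~accepted_mask]
            self.rej[rejected_vox] += 1
            # voxels that were not selected this round keep their streak
            # (only consecutive rejections count)
            if n_new:
                new_pts = cand[kept]
                self.points.append(new_pts)
                self.n_points += n_new
                self._remove_ancestors(np.unique(self._ancestors_of_points(new_pts)))

            if self.maximal:
                # once the acceptance rate collapses, retire voxels that can
                # only produce certain rejections (distribution-preserving;
                # keeps round cost proportional to the remaining free space)
                rounds_since_prune += 1
                if (
                    n_new < 0.05 * sel.size
                    and rounds_since_prune >= 3
                    and self.n_points > 1.02 * self._last_prune_state[0]
                ):
                    self._prune_covered()
                    rounds_since_prune = 0
                ref = trigger_hint if trigger_hint else max(self.n_points, 1)
                if n_new < max(1.0, self.cfg.subdivision_trigger * ref):
                    if self._subdivide():
                        rounds_since_prune = 0
                    else:
                        # resolution floor: keep sampling the residual
                        # slivers, stop after a stall of empty rounds
                        if n_new == 0:
                            floor_stall += 1
                            if floor_stall >= self.cfg.stall_rounds:
                                break
                        else:
                            floor_stall = 0
            else:
                if n_new == 0 and exhausted:
                    bridson_stall += 1
                    if bridson_stall >= 2:
                        break
                else:
                    bridson_stall = 0
        if self.n_points == 0:
            return np.empty((0, self.D))
        return np.concatenate(self.points)


def _check_domain(domain: SpatialDomain) -> None:
    if not isinstance(domain, SpatialDomain):
        raise TypeError("domain must be a SpatialDomain")


def bridson_sample(
    domain: SpatialDomain,
    r: float,
    n_target: int,
    config: SamplerConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Sample up to ``n_target`` points with pairwise distance >= r in the
    extended generation box of ``domain`` (Bridson mode, no subdivision).

    Returning fewer than ``n_target`` points (infeasible request) is a
    reportable, not fatal, outcome: the caller compares ``len(result)``.
    """
    _check_domain(domain)
    if not n_target > 0:
        raise ValueError(f"n_target must be > 0, got {n_target}")
    config = config or SamplerConfig()
    rng = substream(seed if seed is not None else (config.seed or 0), "bridson")
    sampler = _VoxelSampler(
        domain.sampling_extents, r, config, rng, n_target=int(n_target), maximal=False
    )
    return sampler.run()


def maximal_sample(
    domain: SpatialDomain,
    r: float,
    config: SamplerConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Maximal Poisson-disk sample of the extended generation box: no
    additional point can be inserted anywhere at distance >= r from all
    returned points."""
    _check_domain(domain)
    config = config or SamplerConfig()
    rng = substream(seed if seed is not None else (config.seed or 0), "maximal")
    sampler = _VoxelSampler(
        domain.sampling_extents, r, config, rng, n_target=None, maximal=True
    )
    return sampler.run()


def apply_softness(
    points: np.ndarray,
    delta: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Soft-sphere jitter: add independent N(0, delta^2) noise to every
    coordinate. The caller must already have sampled at minimal distance
    r - delta; delta = 0 returns the input unchanged."""
    if delta < 0:
        raise ValueError(f"softness must be >= 0, got {delta}")
    points = np.asarray(points, dtype=float)
    if delta == 0 or points.size == 0:
        return points.copy()
    if rng is None:
        rng = substream(seed if seed is not None else 0, "softness")
    return points + rng.normal(0.0, delta, size=points.shape)


@dataclass
class PlacementReport:
    """Summary of one population placement."""

    name: str
    requested: int | None
    accepted: int
    mode: str
    min_distance: float
    softness: float
    rounds: int = 0
    subdivisions: int = 0
    shortfall: int = 0
    notes: dict = field(default_factory=dict)


def _prior_fields(priors, spec: PopulationSpec, scale: np.ndarray, ext_real):
    """Exclusion fields for previously placed populations, evaluated in real
    coordinates at threshold (d_self + d_prior)/2 - softness."""
    d_self = spec.effective_diameter()
    fields = []
    to_frame = 1.0 / scale
    for prior_pts, prior_diam in priors:
        prior_pts = np.asarray(prior_pts, dtype=float)
        if prior_pts.size == 0:
            continue
        thr = 0.5 * (d_self + float(prior_diam)) - spec.softness
        if thr <= 0:
            continue
        fields.append(
            ExclusionField(
                grid=PointGrid(prior_pts, thr, ext_real),
                threshold=thr,
                to_frame=to_frame,
            )
        )
    return fields


def place_population(
    domain: SpatialDomain,
    spec: PopulationSpec,
    priors=(),
    config: SamplerConfig | None = None,
    mode: str = "maximal",
    n_target: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, PlacementReport]:
    """Place one population in the extended box of ``domain``.

    Sampling happens in the squeezed frame (coordinates multiplied by
    ``spec.anisotropy_scale``) at reduced distance r - delta; candidates are
    also rejected when, in real coordinates, they come closer to any prior
    population point than the mean of the two diameters minus delta. The
    accepted set is un-squeezed and softness-jittered.

    Returns the real-coordinate points (untrimmed) and a report. ``priors``
    is an iterable of ``(points, diameter)`` in real coordinates.
    """
    _check_domain(domain)
    if mode not in ("maximal", "bridson"):
        raise ValueError(f"mode must be 'maximal' or 'bridson', got {mode!r}")
    if spec.min_distance is None:
        raise ValueError("population spec needs min_distance; use tune_min_distance")
    if mode == "bridson" and (n_target is None or n_target <= 0):
        raise ValueError("bridson mode requires n_target > 0")
    config = config or SamplerConfig()
    master = seed if seed is not None else (config.seed or 0)
    rng = substream(master, "place", spec.name)

    scale = spec.scale_vector(domain.ndim)
    r_eff = spec.min_distance - spec.softness
    fields = _prior_fields(priors, spec, scale, domain.sampling_extents)
    sampler = _VoxelSampler(
        domain.sampling_extents * scale,
        r_eff,
        config,
        rng,
        n_target=n_target,
        maximal=(mode == "maximal"),
        fields=fields,
    )
    pts = sampler.run() / scale
    pts = apply_softness(pts, spec.softness, rng=substream(master, "soft", spec.name))
    shortfall = 0
    if n_target is not None and pts.shape[0] < n_target:
        shortfall = n_target - pts.shape[0]
        log.warning(
            "population %s: requested %d points, placed %d (shortfall %d)",
            spec.name, n_target, pts.shape[0], shortfall,
        )
    report = PlacementReport(
        name=spec.name,
        requested=n_target,
        accepted=pts.shape[0],
        mode=mode,
        min_distance=spec.min_distance,
        softness=spec.softness,
        rounds=sampler.rounds,
        subdivisions=sampler.subdivisions,
        shortfall=shortfall,
    )
    return pts, report


def trim_and_shift(
    points: np.ndarray, domain: SpatialDomain
) -> tuple[np.ndarray, np.ndarray]:
    """Remove points in ``trim_margin``-wide strips at the boundaries of the
    extended box and shift so the lowest corner becomes the origin.

    Returns ``(shifted_points, kept_index)`` where ``kept_index`` indexes the
    survivors in the input array (so caller-side ids are preserved)."""
    _check_domain(domain)
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return points.reshape(0, domain.ndim), np.empty(0, dtype=np.int64)
    t = domain.trim_margin
    total = domain.sampling_extents
    keep = np.all((points >= t) & (points < total - t), axis=1)
    kept = np.nonzero(keep)[0]
    return points[kept] - t, kept


def tune_min_distance(
    domain: SpatialDomain,
    spec: PopulationSpec,
    priors=(),
    config: SamplerConfig | None = None,
    density_tolerance: float = 1e-4,
    seed: int | None = None,
    rel_tol: float = 1e-3,
    verify_repeats: int = 3,
    max_bracket: int = 60,
) -> TuningResult:
    """Search the minimal distance d_theta at which maximal packing meets the
    target density of ``spec``.

    Starting from d_1 = 1.05 d_c (the complete-fill anchor), the count of
    trimmed cells produced by a maximal run is a decreasing function of the
    minimal distance; a geometric bracket followed by bisection (relative
    tolerance ``rel_tol``) finds the largest distance whose count still
    reaches n_cell. A final set of ``verify_repeats`` maximal runs at d_theta
    measures the achieved density; ``density_ok`` records whether its mean
    relative deviation from the target is below ``density_tolerance``.
    """
    _check_domain(domain)
    config = config or SamplerConfig()
    master = seed if seed is not None else (config.seed or 0)
    n_cell = int(round(spec.density_per_um(domain.ndim) * domain.volume_um))
    if n_cell < 1:
        raise ValueError("target density yields no cells in this domain")
    d_c = complete_fill_distance(domain.volume_um, n_cell, domain.ndim)
    d_1 = 1.05 * d_c

    def count_at(d: float, i: int) -> int:
        pts, _ = place_population(
            domain,
            spec.with_min_distance(d),
            priors=priors,
            config=config,
            mode="maximal",
            n_target=n_cell,
            seed=int(np.random.SeedSequence([master, i]).generate_state(1)[0] % 2**31),
        )
        _, kept = trim_and_shift(pts, domain)
        return kept.size

    it = 0
    lo = hi = None
    d = d_1
    c = count_at(d, it)
    if c >= n_cell:
        lo = d
        for _ in range(max_bracket):
            it += 1
            d *= 1.05
            c = count_at(d, it)
            if c < n_cell:
                hi = d
                break
            lo = d
        # hi may stay None: degenerate target (e.g. one cell in a huge box);
        # any d >= d_c works and the search stops at its upper bracket.
    else:
        hi = d
        for _ in range(max_bracket):
            it += 1
            # saturation count scales ~ d^-D: jump toward the target count,
            # descending at least 5% and at most 40% per step
            shrink = (max(c, 1) / n_cell) ** (1.0 / domain.ndim)
            d *= min(max(shrink, 0.6), 1.0 / 1.05)
            if d < 1e-6 * d_c:
                raise RuntimeError(
                    f"cannot bracket target density for {spec.name!r}: even "
                    f"d = {d:.3g} um yields only {c} of {n_cell} cells"
                )
            c = count_at(d, it)
            if c >= n_cell:
                lo = d
                break
            hi = d
        if lo is None:
            raise RuntimeError(
                f"cannot bracket target density for {spec.name!r} "
                f"within {max_bracket} shrink steps"
            )

    if hi is not None:
        while (hi - lo) / lo > rel_tol and it < 200:
            it += 1
            mid = 0.5 * (lo + hi)
            if count_at(mid, it) >= n_cell:
                lo = mid
            else:
                hi = mid
    d_theta = lo

    counts = []
    for j in range(verify_repeats):
        it += 1
        counts.append(count_at(d_theta, 10_000 + j))
    achieved = np.mean(counts) / domain.volume_mm
    ok = abs(achieved - spec.density) / spec.density < density_tolerance
    return TuningResult(
        d_theta=float(d_theta),
        achieved_density=float(achieved),
        n_iterations=it,
        d_c=float(d_c),
        d_1=float(d_1),
        density_ok=bool(ok),
        density_tolerance=density_tolerance,
        n_cell=n_cell,
        counts=tuple(int(c) for c in counts),
    )
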