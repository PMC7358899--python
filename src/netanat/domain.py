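"""Spatial domain and population descriptions for cell placement.

All lengths are micrometres; densities are accepted in mm^-D (the unit every
anatomical density is reported in) and converted internally (1 mm = 1e3 um).
Axis convention: axis 0 = mediolateral (x), axis 1 = sagittal (y),
axis 2 = vertical (z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpatialDomain",
    "PopulationSpec",
    "SamplerConfig",
    "TuningResult",
    "UM_PER_MM",
]

UM_PER_MM = 1e3


@dataclass(frozen=True)
class SpatialDomain:
    """An axis-aligned box (um) in which points are generated.

    Generation happens in an *extended* box enlarged by ``extension_margin``
    on every side; cells falling in ``trim_margin``-wide boundary strips of
    the extended box are removed afterwards and the remainder is shifted so
    the lowest corner returns to the origin. This suppresses boundary
    artifacts of the packing process.
    """

    extents: tuple[float, ...]
    extension_margin: float = 25.0
    trim_margin: float = 25.0

    def __post_init__(self):
        ext = tuple(float(e) for e in self.extents)
        object.__setattr__(self, "extents", ext)
        object.__setattr__(self, "extension_margin", float(self.extension_margin))
        object.__setattr__(self, "trim_margin", float(self.trim_margin))
        if len(ext) not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {len(ext)}")
        if any(e <= 0 for e in ext):
            raise ValueError(f"all extents must be positive, got {ext}")
        if not self.extension_margin >= self.trim_margin >= 0:
            raise ValueError(
                "need extension_margin >= trim_margin >= 0, got "
                f"{self.extension_margin} / {self.trim_margin}"
            )

    @property
    def ndim(self) -> int:
        return len(self.extents)

    @property
    def sampling_extents(self) -> np.ndarray:
        """Extents of the extended generation box (um)."""
        return np.asarray(self.extents) + 2.0 * self.extension_margin

    @property
    def volume_um(self) -> float:
        """Volume (3D) or area (2D) of the target box, in um^D."""
        return float(np.prod(self.extents))

    @property
    def volume_mm(self) -> float:
        """Volume/area of the target box in mm^D."""
        return self.volume_um / UM_PER_MM ** self.ndim


@dataclass(frozen=True)
class PopulationSpec:
    """One cell / structure type to be placed.

    Parameters
    ----------
    density : float, optional
        Target number density in mm^-D.
    min_distance : float, optional
        Minimal centre-to-centre distance r (um) between members. ``None``
        when the spec is fed to the distance-tuning search.
    softness : float
        Softness margin delta (um): subtracted from every exclusion distance
        before sampling and re-added as per-coordinate N(0, delta^2) jitter,
        emulating compressible cell bodies.
    diameter : float, optional
        Physical diameter (um) used for exclusion against *other*
        populations; defaults to ``min_distance``.
    anisotropy_scale : tuple, optional
        Per-axis factors applied to coordinates before sampling (the
        "squeezed" frame). E.g. ``(1, 1/3, 1)`` makes the sagittal exclusion
        range three times larger in real space. Defaults to all ones.
    """

    name: str
    density: float | None = None
    min_distance: float | None = None
    softness: float = 0.0
    diameter: float | None = None
    anisotropy_scale: tuple[float, ...] | None = None

    def __post_init__(self):
        # coerce numerics (YAML 1.1 can hand over "1.0e4" as a string)
        for f in ("density", "min_distance", "diameter"):
            v = getattr(self, f)
            if v is not None:
                object.__setattr__(self, f, float(v))
        object.__setattr__(self, "softness", float(self.softness))
        if self.density is not None and not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.softness < 0:
            raise ValueError(f"softness must be >= 0, got {self.softness}")
        if self.min_distance is not None and not self.min_distance > self.softness:
            raise ValueError(
                f"min_distance ({self.min_distance}) must exceed softness "
                f"({self.softness})"
            )
        if self.anisotropy_scale is not None:
            s = tuple(float(v) for v in self.anisotropy_scale)
            if any(v <= 0 for v in s):
                raise ValueError(f"anisotropy_scale must be positive, got {s}")
            object.__setattr__(self, "anisotropy_scale", s)

    def scale_vector(self, ndim: int) -> np.ndarray:
        if self.anisotropy_scale is None:
            return np.ones(ndim)
        s = np.asarray(self.anisotropy_scale, dtype=float)
        if s.size != ndim:
            raise ValueError(
                f"anisotropy_scale has {s.size} components for a {ndim}-D domain"
            )
        return s

    def effective_diameter(self) -> float | None:
        return self.diameter if self.diameter is not None else self.min_distance

    def with_min_distance(self, r: float) -> "PopulationSpec":
        return replace(self, min_distance=float(r))

    def density_per_um(self, ndim: int) -> float:
        if self.density is None:
            raise ValueError(f"population {self.name!r} has no density")
        return self.density / UM_PER_MM ** ndim


@dataclass(frozen=True)
class SamplerConfig:
    """Tunables of the voxel-based Poisson-disk sampler.

    ``voxel_side_divisor``: voxel side = r / divisor; defaults to the
    dimensionality D. Any divisor >= sqrt(D) keeps the voxel diagonal < r and
    hence at most one accepted point per voxel.
    ``candidate_fraction``: fraction of eligible voxels that receive a
    candidate each round.
    ``subdivision_trigger``: when a round adds fewer new points than this
    fraction of the target count, eligible voxels are split into 2^D
    subvoxels and subvoxels fully covered by an existing exclusion ball are
    discarded (maximal mode only).
    ``rejection_limit``: consecutive rejections after which a voxel drops to
    a low-priority pool that is only sampled when the high-priority pool is
    empty; counters reset at every subdivision.
    """

    candidate_fraction: float = 0.20
    subdivision_trigger: float = 6e-4
    rejection_limit: int = 16
    voxel_side_divisor: float | None = None
    min_side_fraction: float = 1.0 / 256.0
    max_rounds: int = 100_000
    stall_rounds: int = 50
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.candidate_fraction <= 1:
            raise ValueError(
                f"candidate_fraction must be in (0, 1], got {self.candidate_fraction}"
            )
        if not self.subdivision_trigger > 0:
            raise ValueError("subdivision_trigger must be > 0")
        if self.rejection_limit < 1:
            raise ValueError("rejection_limit must be >= 1")
        if self.voxel_side_divisor is not None and self.voxel_side_divisor <= 0:
            raise ValueError("voxel_side_divisor must be > 0")

    def divisor(self, ndim: int) -> float:
        return float(self.voxel_side_divisor) if self.voxel_side_divisor else float(ndim)


@dataclass(frozen=True)
class TuningResult:
    """Outcome of the minimal-distance search for a target density."""

    d_theta: float
    achieved_density: float  # per mm^D, mean over verification repeats
    n_iterations: int
    d_c: float
    d_1: float
    density_ok: bool
    density_tolerance: float
    n_cell: int
    counts: tuple[int, ...] = field(default_factory=tuple)
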