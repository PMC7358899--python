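"""Reference model of the rodent cerebellar granular layer.

This module wires the generic machinery into the worked example the package
is validated on: sequential maximal-packing placement of Golgi cells (GoC),
glomeruli (Glo) and granule cells (GC), followed by the anisotropic
GC-to-glomerulus ranged search.

Parameters (literature values used throughout):

- densities: GC 1.9e6 mm^-3, GoC 9500 mm^-3; mossy-fibre entry points
  1650 mm^-2 in 2D with spacing 20.9 um.
- glomerulus density from connectivity bookkeeping: each GC innervates 4.5
  glomeruli on average while each glomerulus receives 15 GC dendrites, so
  there are 4.5 / 15 = 0.3 glomeruli per GC, i.e. 0.57e6 mm^-3.
- minimal distances (= diameters for Glo and GC) at which maximal packing
  reproduces those densities: GoC 45 um (diameter 27 um), Glo 8.39 um, GC
  6.15 um; softness margins 1, 1 and 0.2 um respectively.
- glomeruli are sampled in a frame whose sagittal axis is shrunk to 1/3,
  making their real-space spacing three times larger sagittally.
- GC dendrites reach about four times farther sagittally than
  mediolaterally: the GC-Glo search runs with mediolateral radius 7.85 um
  in a frame with the sagittal coordinate squeezed by 1/4.
"""

from __future__ import annotations

import numpy as np

from ._rng import substream
from .connectivity import SearchSpec, connect_point_to_population
from .domain import PopulationSpec, SamplerConfig, SpatialDomain
from .morphology import QueryPoints
from .placement import place_population, trim_and_shift
from .stats import ConnectionStats, connection_stats

__all__ = [
    "GC_DENSITY", "GOC_DENSITY", "MF_DENSITY", "SYNAPSES_PER_GC",
    "DENDRITES_PER_GLOMERULUS", "glomeruli_per_gc", "glomerulus_density",
    "R_GOC", "R_GLO", "R_GC", "R_MF", "GOC_DIAMETER",
    "GC_GLO_RADIUS", "GC_GLO_SAGITTAL_SCALE", "GLO_SAGITTAL_SQUEEZE",
    "FULL_EXTENTS", "DESK_EXTENTS",
    "population_specs", "generate_positions", "random_positions",
    "connect_gc_glomeruli", "gc_glo_experiment",
]

# densities (per mm^3 unless noted)
GC_DENSITY = 1.9e6
GOC_DENSITY = 9500.0
MF_DENSITY = 1650.0  # per mm^2, 2D entry points
SYNAPSES_PER_GC = 4.5
DENDRITES_PER_GLOMERULUS = 15.0

# minimal distances / diameters (um)
R_GOC = 45.0
GOC_DIAMETER = 27.0
R_GLO = 8.39  # also the glomerulus diameter
R_GC = 6.15  # also the granule-cell diameter
R_MF = 20.9

GOC_SOFTNESS = 1.0
GLO_SOFTNESS = 1.0
GC_SOFTNESS = 0.2

GLO_SAGITTAL_SQUEEZE = 1.0 / 3.0
GC_GLO_RADIUS = 7.85
GC_GLO_SAGITTAL_SCALE = 0.25

FULL_EXTENTS = (700.0, 700.0, 200.0)
DESK_EXTENTS = (350.0, 350.0, 100.0)


def glomeruli_per_gc(
    synapses_per_gc: float = SYNAPSES_PER_GC,
    dendrites_per_glomerulus: float = DENDRITES_PER_GLOMERULUS,
) -> float:
    """Glomeruli per granule cell: 4.5 dendrites out / 15 dendrites in."""
    return synapses_per_gc / dendrites_per_glomerulus


def glomerulus_density(gc_density: float = GC_DENSITY, **kwargs) -> float:
    """Glomerulus density (mm^-3) implied by the dendrite bookkeeping."""
    return glomeruli_per_gc(**kwargs) * gc_density


def population_specs() -> list[PopulationSpec]:
    """The three granular-layer populations in generation order."""
    return [
        PopulationSpec(
            "goc", density=GOC_DENSITY, min_distance=R_GOC,
            softness=GOC_SOFTNESS, diameter=GOC_DIAMETER,
        ),
        PopulationSpec(
            "glo", density=glomerulus_density(), min_distance=R_GLO,
            softness=GLO_SOFTNESS, anisotropy_scale=(1.0, GLO_SAGITTAL_SQUEEZE, 1.0),
        ),
        PopulationSpec(
            "gc", density=GC_DENSITY, min_distance=R_GC, softness=GC_SOFTNESS,
        ),
    ]


def generate_positions(
    extents=DESK_EXTENTS,
    seed: int = 0,
    config: SamplerConfig | None = None,
) -> dict[str, np.ndarray]:
    """Volume-filling positions: sequential maximal Poisson-disk packing of
    GoC, Glo, GC in an extended box with 25 um boundary trim. Returns
    trimmed real-space coordinates per population name."""
    domain = SpatialDomain(extents)
    priors: list[tuple[np.ndarray, float]] = []
    out: dict[str, np.ndarray] = {}
    for spec in population_specs():
        pts, _ = place_population(
            domain, spec, priors=priors, config=config, mode="maximal", seed=seed
        )
        priors.append((pts, spec.effective_diameter()))
        out[spec.name], _ = trim_and_shift(pts, domain)
    return out


def random_positions(extents=DESK_EXTENTS, seed: int = 0) -> dict[str, np.ndarray]:
    """Control condition: GC and Glo drawn uniformly at the same densities,
    with no exclusion constraints."""
    domain = SpatialDomain(extents)
    rng = substream(seed, "random-positions")
    out = {}
    for name, density in [("glo", glomerulus_density()), ("gc", GC_DENSITY)]:
        n = int(round(density / 1e3 ** domain.ndim * domain.volume_um))
        out[name] = rng.random((n, domain.ndim)) * np.asarray(extents)
    return out


def connect_gc_glomeruli(gc_xyz: np.ndarray, glo_xyz: np.ndarray):
    """Anisotropic ranged search from GC somata to distinct glomeruli:
    mediolateral radius 7.85 um with the sagittal coordinate squeezed by
    1/4 (real-space sagittal reach 4 x 7.85 um)."""
    spec = SearchSpec(
        radius=GC_GLO_RADIUS, metric_scale=(1.0, GC_GLO_SAGITTAL_SCALE, 1.0)
    )
    return connect_point_to_population(
        QueryPoints.from_points(gc_xyz),
        QueryPoints.from_points(glo_xyz),
        spec,
        distinct_targets=True,
    )


def gc_glo_experiment(
    extents=DESK_EXTENTS,
    seed: int = 0,
    volume_filling: bool = True,
    config: SamplerConfig | None = None,
) -> tuple[ConnectionStats, float]:
    """One full run of the GC-glomerulus connectivity experiment.

    Returns the degree statistics over all GCs and the mean GC-to-connected-
    glomerulus Euclidean distance (the model's dendrite length).
    """
    if volume_filling:
        pos = generate_positions(extents, seed=seed, config=config)
    else:
        pos = random_positions(extents, seed=seed)
    records = connect_gc_glomeruli(pos["gc"], pos["glo"])
    stats = connection_stats(records, n_source_cells=pos["gc"].shape[0])
    mean_dist = float(records["distance_um"].mean()) if len(records) else float("nan")
    return stats, mean_dist
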