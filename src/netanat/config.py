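"""Declarative pipeline configuration (YAML or plain dicts).

A configuration names the spatial domain, the populations in generation
order (order matters: later populations avoid earlier ones), optional
morphology renderers, and the connection searches to run. Example::

    domain:
      extents: [700, 700, 200]
    populations:
      - {name: goc, density: 9500, min_distance: 45, softness: 1, diameter: 27}
      - {name: glo, density: 0.57e6, min_distance: 8.39, softness: 1,
         anisotropy_scale: [1, 0.3333333333, 1]}
      - {name: gc, density: 1.9e6, min_distance: 6.15, softness: 0.2}
    connections:
      - {name: gc_glo, kind: point, source: gc, target: glo,
         radius: 7.85, metric_scale: [1, 0.25, 1]}
    seed: 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .connectivity import SearchSpec
from .domain import PopulationSpec, SamplerConfig, SpatialDomain
from .morphology import GoCMorphSpec

__all__ = ["ConnectionEntry", "MorphologyEntry", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ConnectionEntry:
    """One connection stage: a point-to-population ranged search
    (``kind='point'``) or a projection search of an axon bundle against a
    rendered cloud (``kind='projection'``)."""

    name: str
    kind: str
    source: str
    target: str
    radius: float
    metric_scale: tuple[float, ...] | None = None
    distinct_targets: bool = True
    max_per_pair: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "radius", float(self.radius))
        if self.kind not in ("point", "projection"):
            raise ValueError(f"unknown connection kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")

    def search_spec(self) -> SearchSpec:
        return SearchSpec(radius=self.radius, metric_scale=self.metric_scale)


@dataclass(frozen=True)
class MorphologyEntry:
    """Morphology renderer attached to a population: Golgi-style dendrites
    (``kind='goc_dendrites'``) or granule-cell axons (``kind='gc_axon'``)."""

    population: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("goc_dendrites", "gc_axon"):
            raise ValueError(f"unknown morphology kind {self.kind!r}")


@dataclass
class PipelineConfig:
    domain: SpatialDomain
    populations: list[PopulationSpec]
    connections: list[ConnectionEntry] = field(default_factory=list)
    morphology: list[MorphologyEntry] = field(default_factory=list)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    segment_length: float = 10.0
    seed: int = 0
    chunks: int = 1

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        known = set(names)
        for m in self.morphology:
            if m.population not in known:
                raise ValueError(f"morphology references unknown population {m.population!r}")
        structures = known | {
            f"{m.population}:{part}"
            for m in self.morphology
            for part in (("dendrites",) if m.kind == "goc_dendrites" else ("aa", "pf"))
        }
        for c in self.connections:
            for side in (c.source, c.target):
                if side not in structures:
                    raise ValueError(
                        f"connection {c.name!r} references unknown structure {side!r}"
                    )

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        dom = SpatialDomain(**{k: v for k, v in d["domain"].items()})
        pops = [
            PopulationSpec(**{**p, "anisotropy_scale": _tup(p.get("anisotropy_scale"))})
            for p in d.get("populations", [])
        ]
        conns = [
            ConnectionEntry(**{**c, "metric_scale": _tup(c.get("metric_scale"))})
            for c in d.get("connections", [])
        ]
        morph = [MorphologyEntry(**m) for m in d.get("morphology", [])]
        sampler = SamplerConfig(**d.get("sampler", {}))
        return cls(
            domain=dom,
            populations=pops,
            connections=conns,
            morphology=morph,
            sampler=sampler,
            segment_length=d.get("segment_length", 10.0),
            seed=int(d.get("seed", 0)),
            chunks=int(d.get("chunks", 1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tup(v):
    return None if v is None else tuple(float(x) for x in v)


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(Path(path))


def goc_morph_spec(params: dict) -> GoCMorphSpec:
    """Build a Golgi morphology spec from a config params dict."""
    fields = {}
    for key in (
        "n_apical", "n_basal", "points_per_apical", "points_per_basal",
        "apical_length", "basal_length", "azimuth_halfwidth_deg",
    ):
        if key in params:
            fields[key] = params[key]
    for key in ("apical_polar_deg", "basal_polar_deg"):
        if key in params:
            fields[key] = tuple(params[key])
    return GoCMorphSpec(**fields)
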