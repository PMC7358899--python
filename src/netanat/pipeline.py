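"""Pipeline orchestration: positions -> point clouds -> connectors -> stats.

One :func:`run_pipeline` call executes a :class:`~netanat.config.PipelineConfig`
end to end and writes every intermediate table into a run directory::

    out/
      positions/<population>.tsv
      querypoints/<population>_dendrites.tsv, <population>_aa.tsv, ...
      connections/<name>.tsv            (or <name>.<chunk>.tsv)
      stats/<name>_degree.json, <population>_nn.json
      manifest.json

Re-running with the same configuration and seed reproduces every file byte
for byte (the manifest records no timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as nio
from ._rng import substream
from .config import ConnectionEntry, PipelineConfig, goc_morph_spec
from .connectivity import (
    cap_connections,
    chunked_connect,
    connect_by_projection,
    connect_point_to_population,
)
from .morphology import (
    AxonBundle,
    QueryPoints,
    assign_segments,
    render_gc_axon,
    render_goc_dendrites,
)
from .placement import place_population, trim_and_shift
from .stats import connection_stats, nearest_neighbor_distances

__all__ = ["run_pipeline", "make_fixture", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    seed: int | None = None,
    mode: str = "maximal",
) -> Path:
    """Run placement, morphology, connectivity and statistics in order.

    Populations are generated sequentially in list order (later populations
    avoid earlier ones); every output table is written under ``out_dir``
    and listed with its row count in ``manifest.json``. Any stage failure
    aborts with a stage-tagged error and the manifest is marked incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    manifest: dict = {
        "seed": seed,
        "mode": mode,
        "stages": {},
        "files": {},
        "complete": False,
    }
    _write_manifest(out, manifest)

    def record_file(relpath: str, rows: int):
        manifest["files"][relpath] = {"rows": int(rows)}

    positions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    structures: dict[str, QueryPoints] = {}
    bundles: dict[str, AxonBundle] = {}

    stage = "placement"
    try:
        priors = []
        for spec in config.populations:
            n_target = None
            if mode == "bridson":
                n_target = int(round(
                    spec.density_per_um(config.domain.ndim)
                    * np.prod(config.domain.sampling_extents)
                ))
            pts, report = place_population(
                config.domain, spec, priors=priors, config=config.sampler,
                mode=mode, n_target=n_target, seed=seed,
            )
            priors.append((pts, spec.effective_diameter()))
            trimmed, kept = trim_and_shift(pts, config.domain)
            ids = kept.astype(np.int64)
            positions[spec.name] = (ids, trimmed)
            rel = f"positions/{spec.name}.tsv"
            nio.write_positions(out / rel, ids, trimmed)
            record_file(rel, len(ids))
            density = len(ids) / config.domain.volume_mm
            nn = (
                float(nearest_neighbor_distances(trimmed).min())
                if len(ids) > 1 else float("nan")
            )
            log.info(
                "population %s: generated %d, kept %d (density %.4g mm^-%d, "
                "min NN %.3g um)",
                spec.name, report.accepted, len(ids), density,
                config.domain.ndim, nn,
            )
            manifest["stages"].setdefault("placement", {})[spec.name] = {
                "generated": report.accepted,
                "kept": len(ids),
                "density_per_mm": density,
                "min_distance": spec.min_distance,
                "softness": spec.softness,
            }

        stage = "morphology"
        for entry in config.morphology:
            ids, xyz = positions[entry.population]
            if entry.kind == "goc_dendrites":
                qp = render_goc_dendrites(
                    xyz, goc_morph_spec(entry.params), seed=seed, cell_ids=ids
                )
                qp = assign_segments(qp, entry.params.get("segment_length", config.segment_length))
                key = f"{entry.population}:dendrites"
                structures[key] = qp
                rel = f"querypoints/{entry.population}_dendrites.tsv"
                nio.write_querypoints(out / rel, qp)
                record_file(rel, len(qp))
            else:  # gc_axon
                height = entry.params.get("aa_height", (0.0, 0.0))
                if isinstance(height, (list, tuple)):
                    height = tuple(float(h) for h in height)
                aa, pf = render_gc_axon(
                    xyz,
                    aa_height=height,
                    pf_half_length=float(entry.params.get("pf_half_length", 1000.0)),
                    seed=seed,
                    cell_ids=ids,
                )
                for key, bundle in [("aa", aa), ("pf", pf)]:
                    bundles[f"{entry.population}:{key}"] = bundle
                    rel = f"querypoints/{entry.population}_{key}.tsv"
                    nio.write_bundle(out / rel, bundle)
                    record_file(rel, len(bundle))

        stage = "connectivity"
        for entry in config.connections:
            records = _run_connection(entry, positions, structures, bundles, config)
            if entry.max_per_pair is not None:
                records = cap_connections(records, entry.max_per_pair)
            if config.chunks > 1 and len(records):
                blocks = np.array_split(np.arange(len(records)), config.chunks)
                for c, idx in enumerate(blocks):
                    rel = f"connections/{entry.name}.{c}.tsv"
                    nio.write_connections(out / rel, records.iloc[idx])
                    record_file(rel, len(idx))
            else:
                rel = f"connections/{entry.name}.tsv"
                nio.write_connections(out / rel, records)
                record_file(rel, len(records))

            stage = "stats"
            n_src = _n_source_cells(entry, positions)
            stats = connection_stats(records, n_source_cells=n_src)
            rel = f"stats/{entry.name}_degree.json"
            (out / "stats").mkdir(exist_ok=True)
            with open(out / rel, "w") as fh:
                json.dump(stats.as_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            record_file(rel, 1)
            stage = "connectivity"

        stage = "stats"
        for name, (ids, xyz) in positions.items():
            if len(ids) < 2:
                continue
            nn = nearest_neighbor_distances(xyz)
            rel = f"stats/{name}_nn.json"
            (out / "stats").mkdir(exist_ok=True)
            with open(out / rel, "w") as fh:
                json.dump(
                    {"n": len(ids), "nn_mean": float(nn.mean()),
                     "nn_min": float(nn.min()), "nn_max": float(nn.max())},
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")
            record_file(rel, 1)
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _write_manifest(out, manifest)
        raise PipelineError(stage, str(exc)) from exc

    manifest["complete"] = True
    _write_manifest(out, manifest)
    return out


def _structure(name, positions, structures, bundles):
    if name in structures:
        return structures[name]
    if name in bundles:
        return bundles[name]
    if name in positions:
        ids, xyz = positions[name]
        return QueryPoints.from_points(xyz, cell_id=ids)
    raise KeyError(f"unknown structure {name!r}")


def _run_connection(entry: ConnectionEntry, positions, structures, bundles, config):
    src = _structure(entry.source, positions, structures, bundles)
    tgt = _structure(entry.target, positions, structures, bundles)
    if entry.kind == "projection":
        if not isinstance(src, AxonBundle):
            raise ValueError(
                f"connection {entry.name!r}: projection source must be an axon bundle"
            )
        return connect_by_projection(src, tgt, entry.radius)
    if isinstance(src, AxonBundle) or isinstance(tgt, AxonBundle):
        raise ValueError(f"connection {entry.name!r}: point search needs point clouds")
    if entry.distinct_targets:
        return connect_point_to_population(src, tgt, entry.search_spec())
    return chunked_connect(src, tgt, entry.search_spec(), n_chunks=1)


def _n_source_cells(entry: ConnectionEntry, positions) -> int:
    pop = entry.source.split(":")[0]
    if pop in positions:
        return len(positions[pop][0])
    return 1


def make_fixture(kind: str, size: int, seed: int = 0):
    """Deterministic miniature datasets for tests and documentation.

    Kinds: ``uniform-2D`` / ``uniform-3D`` (random points in a unit-ish
    box), ``two-population`` (two interleaved point sets with known
    separations), ``toy-axon-bundle`` (parallel axons with hand-checkable
    coordinates plus a small target cloud).
    """
    rng = substream(seed, "fixture", kind)
    if kind == "uniform-2D":
        return rng.random((size, 2)) * 100.0
    if kind == "uniform-3D":
        return rng.random((size, 3)) * 100.0
    if kind == "two-population":
        a = rng.random((size, 3)) * 100.0
        b = rng.random((size, 3)) * 100.0
        return a, b
    if kind == "toy-axon-bundle":
        # parallel fibers along x at 10 um vertical spacing
        n = size
        start = np.column_stack([np.zeros(n), np.full(n, 5.0), 10.0 * np.arange(n)])
        end = start.copy()
        end[:, 0] = 100.0
        bundle = AxonBundle(
            cell_id=np.arange(n), start=start, end=end, axis=0,
            arc_origin=start[:, 0], arc_offset=np.zeros(n),
        )
        targets = QueryPoints.from_points(
            rng.random((20 * max(size, 1), 3)) * np.array([120.0, 10.0, 10.0 * n])
        )
        return bundle, targets
    raise ValueError(f"unknown fixture kind {kind!r}")
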