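"""Connectivity searches against brute-force oracles: ranged search,
anisotropic ellipsoid membership, projection method, capping, chunking."""

import numpy as np
import pandas as pd
import pytest

from netanat.connectivity import (
    SearchSpec,
    cap_connections,
    chunked_connect,
    connect_by_projection,
    connect_point_to_population,
    ranged_search,
)
from netanat.morphology import AxonBundle, QueryPoints

from conftest import brute_force_pairs


def _cloud(rng, n, box=(100.0, 100.0, 100.0), id_offset=0):
    return QueryPoints.from_points(
        rng.random((n, 3)) * np.asarray(box), cell_id=np.arange(n) + id_offset
    )


def _record_pairs(records: pd.DataFrame):
    return set(zip(records["source_id"].tolist(), records["target_id"].tolist()))


class TestRangedSearch:
    @pytest.mark.parametrize("radius", [3.0, 8.0, 20.0])
    def test_matches_brute_force(self, rng, radius):
        src = _cloud(rng, 200)
        tgt = _cloud(rng, 300)
        rec = ranged_search(src, tgt, SearchSpec(radius=radius))
        oracle = brute_force_pairs(src.coords, tgt.coords, radius)
        assert _record_pairs(rec) == oracle

    def test_tree_side_invariance(self, rng):
        src = _cloud(rng, 150)
        tgt = _cloud(rng, 60)
        recs = [
            ranged_search(src, tgt, SearchSpec(radius=12.0, tree_side=side))
            for side in ("auto", "source", "target")
        ]
        for other in recs[1:]:
            pd.testing.assert_frame_equal(recs[0], other)

    def test_disjoint_clouds_empty(self, rng):
        src = _cloud(rng, 20, box=(10.0, 10.0, 10.0))
        tgt = QueryPoints.from_points(rng.random((20, 3)) * 10 + 500.0)
        rec = ranged_search(src, tgt, SearchSpec(radius=1e-6))
        assert len(rec) == 0

    def test_real_distance_reported_under_scaling(self, rng):
        src = _cloud(rng, 50)
        tgt = _cloud(rng, 50)
        rec = ranged_search(src, tgt, SearchSpec(radius=10.0, metric_scale=(1, 0.25, 1)))
        for _, row in rec.head(20).iterrows():
            s = src.coords[src.cell_id == row.source_id][0]
            t = tgt.coords[tgt.cell_id == row.target_id][0]
            assert row.distance_um == pytest.approx(np.linalg.norm(s - t))

    def test_scaled_search_is_ellipsoid_membership(self, rng):
        # scaling by s and searching radius r == real-space ellipsoid with
        # semi-axes r/s_axis
        scale = np.array([1.0, 0.25, 1.0])
        r = 7.85
        src = _cloud(rng, 100)
        tgt = _cloud(rng, 200)
        rec = ranged_search(src, tgt, SearchSpec(radius=r, metric_scale=tuple(scale)))
        diff = src.coords[:, None, :] - tgt.coords[None, :, :]
        inside = np.sqrt(((diff * scale) ** 2).sum(-1)) <= r
        oracle = set(zip(*map(list, np.nonzero(inside))))
        assert _record_pairs(rec) == oracle

    def test_dimension_mismatch_rejected(self, rng):
        src = QueryPoints.from_points(rng.random((5, 2)))
        tgt = _cloud(rng, 5)
        with pytest.raises(ValueError):
            ranged_search(src, tgt, SearchSpec(radius=1.0))

    def test_empty_cloud_rejected(self, rng):
        with pytest.raises(ValueError):
            ranged_search(QueryPoints.empty(3), _cloud(rng, 5), SearchSpec(radius=1.0))


class TestConnectPointToPopulation:
    def test_equidistant_targets_both_connected(self):
        src = QueryPoints.from_points([[0.0, 0.0, 0.0]])
        tgt = QueryPoints.from_points([[3.0, 0.0, 0.0], [-3.0, 0.0, 0.0]])
        rec = connect_point_to_population(src, tgt, SearchSpec(radius=5.0))
        assert len(rec) == 2

    def test_distinct_rule_keeps_nearest_point_per_cell(self):
        src = QueryPoints.from_points([[0.0, 0.0, 0.0]])
        # one target cell contributes two in-range points
        tgt = QueryPoints(
            coords=np.array([[4.0, 0, 0], [2.0, 0, 0]]),
            cell_id=np.array([7, 7]),
            compartment=np.array(["soma", "soma"], dtype=object),
            segment_id=np.array([0, 1]),
            arc_length=np.zeros(2),
        )
        rec = connect_point_to_population(src, tgt, SearchSpec(radius=5.0))
        assert len(rec) == 1
        assert rec.iloc[0].distance_um == pytest.approx(2.0)
        assert rec.iloc[0].target_segment == 1

    def test_toy_instance_matches_ellipsoid_oracle(self, rng):
        scale = np.array([1.0, 0.25, 1.0])
        r = 7.85
        gcs = _cloud(rng, 20, box=(50.0, 50.0, 50.0))
        glos = _cloud(rng, 30, box=(50.0, 50.0, 50.0))
        rec = connect_point_to_population(
            gcs, glos, SearchSpec(radius=r, metric_scale=tuple(scale))
        )
        diff = gcs.coords[:, None, :] - glos.coords[None, :, :]
        inside = np.sqrt(((diff * scale) ** 2).sum(-1)) <= r
        assert _record_pairs(rec) == set(zip(*map(list, np.nonzero(inside))))


class TestConnectByProjection:
    def _bundle(self):
        # one axon along x from (0, 5, 5) to (50, 5, 5)
        return AxonBundle(
            cell_id=[0], start=[[0.0, 5.0, 5.0]], end=[[50.0, 5.0, 5.0]], axis=0
        )

    def test_target_on_line_within_extent(self):
        tgt = QueryPoints.from_points([[25.0, 5.0, 5.0]])
        rec = connect_by_projection(self._bundle(), tgt, radius=2.0)
        assert len(rec) == 1
        assert rec.iloc[0].distance_um == 0.0
        assert rec.iloc[0].syn_x == pytest.approx(25.0)

    def test_backtrace_rejects_beyond_endpoint(self):
        # laterally within radius, but past the axon tip along the axis
        tgt = QueryPoints.from_points([[60.0, 5.5, 5.0]])
        rec = connect_by_projection(self._bundle(), tgt, radius=2.0)
        assert len(rec) == 0

    def test_path_length_continues_arc_convention(self):
        bundle = AxonBundle(
            cell_id=[0], start=[[-10.0, 5.0, 5.0]], end=[[30.0, 5.0, 5.0]],
            axis=0, arc_origin=[10.0], arc_offset=[100.0],
        )
        tgt = QueryPoints.from_points([[25.0, 5.0, 6.0]])
        rec = connect_by_projection(bundle, tgt, radius=2.0)
        assert rec.iloc[0].path_length_um == pytest.approx(100.0 + 15.0)
        assert rec.iloc[0].distance_um == pytest.approx(1.0)

    def test_matches_dense_bead_chain_search(self, rng):
        # the projection search is the cylinder limit of a 3D ranged search
        # against axons resampled as bead chains; agreement holds exactly
        # away from the decision boundary (within one bead spacing)
        n_axons, n_targets, radius, spacing = 50, 500, 3.0, 0.1
        y = rng.random(n_axons) * 50
        z = rng.random(n_axons) * 50
        x0 = rng.random(n_axons) * 20
        x1 = x0 + 20 + rng.random(n_axons) * 30
        bundle = AxonBundle(
            cell_id=np.arange(n_axons),
            start=np.column_stack([x0, y, z]),
            end=np.column_stack([x1, y, z]),
            axis=0,
        )
        targets = QueryPoints.from_points(rng.random((n_targets, 3)) * np.array([70, 50, 50]))
        rec = connect_by_projection(bundle, targets, radius=radius)
        got = _record_pairs(rec)

        beads, owners = [], []
        for a in range(n_axons):
            xs = np.arange(x0[a], x1[a] + spacing / 2, spacing)
            beads.append(np.column_stack([xs, np.full_like(xs, y[a]), np.full_like(xs, z[a])]))
            owners.append(np.full(len(xs), a))
        beads = np.concatenate(beads)
        owners = np.concatenate(owners)
        d = np.linalg.norm(beads[:, None, :] - targets.coords[None, :, :], axis=2)
        bi, tj = np.nonzero(d <= radius)
        bead_pairs = set(zip(owners[bi].tolist(), tj.tolist()))

        for a, t in got ^ bead_pairs:
            # disagreements must sit within discretization tolerance of the
            # cylinder boundary (lateral or axial)
            p = targets.coords[t]
            lat = np.hypot(p[1] - y[a], p[2] - z[a])
            axial = min(abs(p[0] - x0[a]), abs(p[0] - x1[a]))
            near_lateral = abs(lat - radius) <= spacing
            near_axial = axial <= radius + spacing
            assert near_lateral or near_axial

    def test_beads_converge_to_projection(self, rng):
        # symmetric difference shrinks monotonically as bead spacing -> 0
        n_axons, n_targets, radius = 10, 200, 3.0
        y = rng.random(n_axons) * 30
        z = rng.random(n_axons) * 30
        bundle = AxonBundle(
            cell_id=np.arange(n_axons),
            start=np.column_stack([np.zeros(n_axons), y, z]),
            end=np.column_stack([np.full(n_axons, 40.0), y, z]),
            axis=0,
        )
        targets = QueryPoints.from_points(rng.random((n_targets, 3)) * np.array([40, 30, 30]))
        got = _record_pairs(connect_by_projection(bundle, targets, radius=radius))
        mismatches = []
        for spacing in (2.0, 0.5, 0.05):
            beads, owners = [], []
            for a in range(n_axons):
                xs = np.arange(0.0, 40.0 + spacing / 2, spacing)
                beads.append(np.column_stack([xs, np.full_like(xs, y[a]), np.full_like(xs, z[a])]))
                owners.append(np.full(len(xs), a))
            beads = np.concatenate(beads); owners = np.concatenate(owners)
            d = np.linalg.norm(beads[:, None, :] - targets.coords[None, :, :], axis=2)
            bi, tj = np.nonzero(d <= radius)
            pairs = set(zip(owners[bi].tolist(), tj.tolist()))
            mismatches.append(len(got ^ pairs))
        assert mismatches[0] >= mismatches[1] >= mismatches[2]

    def test_non_parallel_axon_rejected(self):
        with pytest.raises(ValueError):
            AxonBundle(cell_id=[0], start=[[0, 0, 0]], end=[[10, 1, 0]], axis=0)


class TestCapConnections:
    def _records(self):
        return pd.DataFrame({
            "source_id": [1] * 5,
            "target_id": [2] * 5,
            "target_segment": [4, 3, 2, 1, 0],
            "distance_um": [5.0, 4.0, 3.0, 2.0, 1.0],
            "path_length_um": [np.nan] * 5,
            "syn_x": [0.0] * 5, "syn_y": [0.0] * 5, "syn_z": [0.0] * 5,
        })

    def test_unlimited_is_identity(self):
        rec = self._records()
        out = cap_connections(rec, None)
        assert len(out) == 5

    def test_keeps_nearest(self):
        out = cap_connections(self._records(), 2)
        assert sorted(out.distance_um) == [1.0, 2.0]

    def test_invalid_cap(self):
        with pytest.raises(ValueError):
            cap_connections(self._records(), 0)

    def test_permutation_invariant(self, rng):
        rec = self._records().sample(frac=1.0, random_state=3).reset_index(drop=True)
        out1 = cap_connections(self._records(), 3)
        out2 = cap_connections(rec, 3)
        pd.testing.assert_frame_equal(out1, out2)


class TestChunkedConnect:
    def test_single_chunk_equals_serial(self, rng):
        src = _cloud(rng, 100)
        tgt = _cloud(rng, 100)
        spec = SearchSpec(radius=15.0)
        pd.testing.assert_frame_equal(
            chunked_connect(src, tgt, spec, 1), ranged_search(src, tgt, spec)
        )

    @pytest.mark.parametrize("n_chunks", [2, 4, 7])
    def test_chunking_preserves_result_set(self, rng, n_chunks):
        src = _cloud(rng, 250)
        tgt = _cloud(rng, 250)
        spec = SearchSpec(radius=12.0)
        serial = ranged_search(src, tgt, spec)
        chunked = chunked_connect(src, tgt, spec, n_chunks)
        pd.testing.assert_frame_equal(serial, chunked)
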