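"""Background removal, Euclidean clustering, and serial cluster tracking."""

import numpy as np
import pytest

from marmotrack.lidar import (
    BackgroundModel,
    ClusterParams,
    ClusterTracker,
    PointCloud,
    build_background,
    extract_clusters,
    remove_background,
)


def brute_force_components(points: np.ndarray, tol: float) -> list[set[int]]:
    """O(n^2) union-find over pairwise distances — the clustering oracle."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= tol:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def blob(rng, center, n=80, sigma=25.0):
    return rng.normal(center, sigma, size=(n, 3))


class TestBackground:
    def test_model_marks_exactly_the_scanned_voxels(self, rng):
        pts = rng.uniform(0, 500, size=(200, 3))
        bg = build_background([PointCloud(0.0, pts)], voxel_size=50.0)
        assert np.all(bg.contains(pts))

    def test_union_is_idempotent(self, rng):
        pts = rng.uniform(0, 500, size=(200, 3))
        one = build_background([PointCloud(0.0, pts)], 50.0)
        two = build_background([PointCloud(0.0, pts), PointCloud(1.0, pts)], 50.0)
        assert one.occupied == two.occupied

    def test_coarser_voxels_occupy_superset_volume(self, rng):
        pts = rng.uniform(0, 500, size=(300, 3))
        coarse = build_background([PointCloud(0.0, pts)], 50.0)
        fine = build_background([PointCloud(0.0, pts)], 25.0)
        probe = rng.uniform(0, 500, size=(2000, 3))
        in_fine = fine.contains(probe)
        in_coarse = coarse.contains(probe)
        assert np.all(in_coarse[in_fine])

    def test_background_cloud_removed_entirely(self, rng):
        pts = rng.uniform(0, 500, size=(200, 3))
        bg = build_background([PointCloud(0.0, pts)], 50.0)
        out = remove_background(PointCloud(1.0, pts), bg)
        assert len(out.points) == 0

    def test_foreground_blob_survives_subtraction(self, rng):
        mesh = rng.uniform(0, 300, size=(500, 3))
        bg = build_background([PointCloud(0.0, mesh)], 30.0)
        fg = blob(rng, (1000.0, 1000.0, 1000.0), n=200)
        mixed = PointCloud(1.0, np.vstack([mesh, fg]))
        out = remove_background(mixed, bg)
        # exactly the 200 free-space points survive (set-difference oracle)
        assert len(out.points) == 200
        assert np.allclose(np.sort(out.points, axis=0), np.sort(fg, axis=0))

    def test_empty_inputs(self):
        with pytest.raises(ValueError):
            build_background([], 50.0)
        bg = BackgroundModel(50.0, set())
        assert len(remove_background(PointCloud(0.0, np.zeros((0, 3))), bg).points) == 0


class TestClustering:
    def test_two_separated_blobs(self, rng):
        a = blob(rng, (0.0, 0.0, 0.0), n=120, sigma=30)
        b = blob(rng, (1000.0, 0.0, 0.0), n=120, sigma=30)
        clusters = extract_clusters(
            PointCloud(0.0, np.vstack([a, b])), ClusterParams(tolerance=50.0)
        )
        assert len(clusters) == 2
        means = sorted([tuple(c.centroid) for c in clusters])
        assert np.linalg.norm(np.array(means[0]) - a.mean(axis=0)) < 10
        assert np.linalg.norm(np.array(means[1]) - b.mean(axis=0)) < 10

    def test_oversize_blob_rejected_by_s2_gate(self):
        # dense 600 mm grid: a single connected component above the S2 gate
        axis = np.arange(0.0, 601.0, 50.0)
        big = np.stack(np.meshgrid(axis, axis, axis), axis=-1).reshape(-1, 3)
        assert extract_clusters(PointCloud(0.0, big), ClusterParams(tolerance=80.0)) == []

    def test_undersize_blob_rejected_by_s1_gate(self, rng):
        tiny = blob(rng, (0, 0, 0), n=30, sigma=8.0)  # ~60 mm extent
        clusters = extract_clusters(PointCloud(0.0, tiny), ClusterParams(tolerance=50.0))
        assert clusters == []

    def test_empty_cloud(self):
        assert extract_clusters(PointCloud(0.0, np.zeros((0, 3))), ClusterParams()) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_connected_components(self, seed):
        """Clustering equals the O(n^2) union-find oracle on random clouds."""
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0, 1500, size=(4, 3))
        pts = np.vstack([blob(rng, c, n=60, sigma=40) for c in centers])
        tol = 60.0
        oracle = brute_force_components(pts, tol)
        params = ClusterParams(tolerance=tol)
        oracle_accepted = []
        for comp in oracle:
            member = pts[sorted(comp)]
            extent = float(np.max(member.max(axis=0) - member.min(axis=0)))
            if params.s1 <= extent <= params.s2:
                oracle_accepted.append(
                    frozenset(map(tuple, np.round(member, 9)))
                )
        got = {
            frozenset(map(tuple, np.round(c.points, 9)))
            for c in extract_clusters(PointCloud(0.0, pts), params)
        }
        assert got == set(oracle_accepted)

    def test_accepted_clusters_partition_their_points(self, rng):
        pts = np.vstack([blob(rng, c, n=80, sigma=35) for c in rng.uniform(0, 1200, (3, 3))])
        clusters = extract_clusters(PointCloud(0.0, pts), ClusterParams(tolerance=60.0))
        seen = set()
        for c in clusters:
            keys = set(map(tuple, c.points))
            assert not (keys & seen)
            seen |= keys

    def test_larger_tolerance_never_more_components(self, rng):
        pts = rng.uniform(0, 800, size=(300, 3))
        from marmotrack.lidar import _connected_labels

        n_small = len(np.unique(_connected_labels(pts, 40.0)))
        n_large = len(np.unique(_connected_labels(pts, 80.0)))
        assert n_large <= n_small


class TestClusterTracking:
    def _cluster_at(self, center):
        pts = np.asarray(center, dtype=float) + np.array(
            [[-60, 0, 0], [60, 0, 0], [0, 60, 0], [0, -60, 0]]
        )
        from marmotrack.lidar import Cluster

        return Cluster(points=pts, centroid=pts.mean(axis=0), extent=120.0)

    def test_track_extended_within_gate(self):
        tracker = ClusterTracker(gate=300.0)
        tracker.update([self._cluster_at((0, 0, 0))], 0.0)
        tracker.update([self._cluster_at((100, 0, 0))], 0.1)
        assert len(tracker.tracks) == 1
        assert len(tracker.tracks[0].samples) == 2

    def test_jump_beyond_gate_issues_new_serial(self):
        tracker = ClusterTracker(gate=300.0, dropout_window=0.5)
        tracker.update([self._cluster_at((0, 0, 0))], 0.0)
        tracker.update([self._cluster_at((700, 0, 0))], 0.1)
        serials = [tr.serial_id for tr in tracker.tracks]
        assert serials == [0, 1]

    def test_crossing_assignment_matches_two_permutation_oracle(self, rng):
        """Hungarian assignment beats/equals both 2-permutations on crossings."""
        for _ in range(20):
            t0 = rng.uniform(0, 1000, size=(2, 3))
            t1 = t0 + rng.uniform(-150, 150, size=(2, 3))
            tracker = ClusterTracker(gate=400.0)
            tracker.update([self._cluster_at(c) for c in t0], 0.0)
            tracker.update([self._cluster_at(c) for c in t1], 0.1)
            cost_kept = sum(
                np.linalg.norm(tr.samples[1][1] - tr.samples[0][1])
                for tr in tracker.tracks
                if len(tr.samples) == 2
            )
            ident = np.linalg.norm(t1[0] - t0[0]) + np.linalg.norm(t1[1] - t0[1])
            swap = np.linalg.norm(t1[1] - t0[0]) + np.linalg.norm(t1[0] - t0[1])
            if len([tr for tr in tracker.tracks if len(tr.samples) == 2]) == 2:
                assert cost_kept <= min(ident, swap) + 1e-9

    def test_serials_unique_nondecreasing_never_reused(self, rng):
        tracker = ClusterTracker(gate=200.0, dropout_window=0.3)
        for k in range(30):
            centers = rng.uniform(0, 2000, size=(rng.integers(0, 4), 3))
            tracker.update([self._cluster_at(c) for c in centers], k * 0.14)
        serials = [tr.serial_id for tr in tracker.tracks]
        assert serials == sorted(serials)
        assert len(serials) == len(set(serials))
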