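"""Lidar point-cloud pipeline: background removal, clustering, centroid tracking.

A laser scanner watching the home cage returns a mixture of static returns
(cage mesh, feeders, bedding) and moving returns (the animals).  The static
scene is captured once, without animals, as a voxel occupancy model;
at run time any point falling in an occupied voxel is discarded.  The
remaining foreground points are grouped by Euclidean cluster extraction —
connected components under a pairwise linking distance — and components
are kept only when their spatial extent falls between the minimum and
maximum animal-size gates S1 = 100 mm and S2 = 500 mm.  Each accepted
cluster's centroid stands in for the animal's position, and centroids are
linked over time into serially numbered tracks; a broken trajectory gets a
fresh serial number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class PointCloud:
    """One timestamped scan in the cage frame (mm); may be empty."""

    timestamp: float
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class ClusterParams:
    """Euclidean-clustering parameters: linking tolerance and size gates (mm)."""

    tolerance: float = 50.0
    s1: float = 100.0  # minimum accepted cluster extent
    s2: float = 500.0  # maximum accepted cluster extent

    def __post_init__(self) -> None:
        if not (0 < self.s1 < self.s2):
            raise ValueError("size gates must satisfy 0 < S1 < S2")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class Cluster:
    points: np.ndarray
    centroid: np.ndarray
    extent: float  # max axis-aligned span, mm


@dataclass
class LidarTrack:
    """Serially numbered centroid track; a break gets a new serial."""

    serial_id: int
    samples: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def last_time(self) -> float:
        return self.samples[-1][0]

    @property
    def last_centroid(self) -> np.ndarray:
        return self.samples[-1][1]


class BackgroundModel:
    """Voxel occupancy built from animal-free calibration scans."""

    def __init__(self, voxel_size: float, occupied: set[tuple[int, int, int]]):
        if voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.voxel_size = float(voxel_size)
        self.occupied = occupied

    @staticmethod
    def voxel_indices(points: np.ndarray, voxel_size: float) -> np.ndarray:
        return np.floor(np.asarray(points, dtype=float) / voxel_size).astype(np.int64)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Mask of points falling in background-occupied voxels."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        if pts.size == 0:
            return np.zeros(0, dtype=bool)
        idx = self.voxel_indices(pts, self.voxel_size)
        return np.fromiter(
            (tuple(i) in self.occupied for i in idx), dtype=bool, count=len(idx)
        )


def build_background(scans: list[PointCloud], voxel_size: float = 30.0) -> BackgroundModel:
    """Union of occupied voxels across animal-free scans."""
    if not scans:
        raise ValueError("need at least one background scan")
    occupied: set[tuple[int, int, int]] = set()
    for scan in scans:
        if scan.points.size == 0:
            continue
        idx = BackgroundModel.voxel_indices(scan.points, voxel_size)
        occupied.update(map(tuple, idx))
    return BackgroundModel(voxel_size, occupied)


def remove_background(cloud: PointCloud, bg: BackgroundModel) -> PointCloud:
    """Retain only points whose voxel is free in the background model."""
    if cloud.points.size == 0:
        return cloud
    keep = ~bg.contains(cloud.points)
    return PointCloud(cloud.timestamp, cloud.points[keep])


def _connected_labels(points: np.ndarray, tolerance: float) -> np.ndarray:
    """Component label per point under the pairwise linking distance."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(tolerance, output_type="ndarray")
    if len(pairs) == 0:
        return np.arange(n)
    data = np.ones(len(pairs), dtype=np.int8)
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def extract_clusters(cloud: PointCloud, params: ClusterParams) -> list[Cluster]:
    """Euclidean cluster extraction with S1/S2 extent gates.

    Components whose maximum axis-aligned span lies outside [S1, S2] are
    discarded — too small to be an animal (noise, a tail tip) or too large
    (merged blobs, un-subtracted structure).
    """
    pts = cloud.points
    if pts.size == 0:
        return []
    labels = _connected_labels(pts, params.tolerance)
    clusters = []
    for lab in np.unique(labels):
        member = pts[labels == lab]
        extent = float(np.max(member.max(axis=0) - member.min(axis=0)))
        if params.s1 <= extent <= params.s2:
            clusters.append(
                Cluster(points=member, centroid=member.mean(axis=0), extent=extent)
            )
    return clusters


class ClusterTracker:
    """Links per-scan cluster centroids into serially numbered tracks.

    Assignment is a global minimum-cost matching (Hungarian) with matches
    beyond ``gate`` forbidden; unmatched clusters open new tracks with the
    next serial number, and a track silent for longer than
    ``dropout_window`` is closed.  Serials are never reused.
    """

    def __init__(self, gate: float = 300.0, dropout_window: float = 1.0):
        self.gate = float(gate)
        self.dropout_window = float(dropout_window)
        self.active: list[LidarTrack] = []
        self.closed: list[LidarTrack] = []
        self._next_serial = 0

    def _open(self, t: float, centroid: np.ndarray) -> None:
        track = LidarTrack(self._next_serial, [(t, centroid)])
        self._next_serial += 1
        self.active.append(track)

    def update(self, clusters: list[Cluster], t: float) -> None:
        # close stale tracks first so they cannot claim a cluster
        still = []
        for tr in self.active:
            if t - tr.last_time > self.dropout_window:
                self.closed.append(tr)
            else:
                still.append(tr)
        self.active = still

        centroids = [c.centroid for c in clusters]
        matched_track: dict[int, int] = {}
        if self.active and centroids:
            cost = np.array(
                [[np.linalg.norm(tr.last_centroid - c) for c in centroids]
                 for tr in self.active]
            )
            big = 1e9
            cost_gated = np.where(cost <= self.gate, cost, big)
            rows, cols = linear_sum_assignment(cost_gated)
            for r, c in zip(rows, cols):
                if cost[r, c] <= self.gate:
                    matched_track[c] = r
        for ci, centroid in enumerate(centroids):
            if ci in matched_track:
                self.active[matched_track[ci]].samples.append((t, centroid))
            else:
                self._open(t, centroid)

    @property
    def tracks(self) -> list[LidarTrack]:
        return sorted(self.closed + self.active, key=lambda tr: tr.serial_id)


def track_clusters(
    tracker: ClusterTracker, clusters: list[Cluster], t: float
) -> ClusterTracker:
    """Functional wrapper around :meth:`ClusterTracker.update`."""
    tracker.update(clusters, t)
    return tracker


def run_lidar_pipeline(
    clouds: list[PointCloud],
    background: BackgroundModel,
    params: ClusterParams | None = None,
    gate: float = 300.0,
    dropout_window: float = 1.0,
) -> list[LidarTrack]:
    """Background-subtract, cluster, and track a scan sequence."""
    params = params or ClusterParams()
    tracker = ClusterTracker(gate=gate, dropout_window=dropout_window)
    for cloud in clouds:
        fg = remove_background(cloud, background)
        tracker.update(extract_clusters(fg, params), cloud.timestamp)
    return tracker.tracks
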