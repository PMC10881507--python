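"""Video pipeline: per-camera 2D detections to per-tick 3D body positions.

An object detector watching each of the four front cameras emits bounding
boxes for classes like ``body``, ``face`` or ``grooming``.  This module
takes those per-camera streams, snaps them onto a common analysis tick
grid, hypothesises which boxes in different cameras are the same animal
(cross-view association by triangulation residual), and triangulates the
bounding-box centres into cage-frame 3D positions.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .geometry import (
    CageModel,
    CameraModel,
    PixelObservation,
    triangulate,
    triangulate_pixels,
)

DET_CLASSES = ("face", "body", "grooming", "ball", "hammock")


@dataclass(frozen=True)
class Detection2D:
    """One detector box in one camera frame."""

    camera_id: str
    timestamp: float
    det_class: str
    bbox: tuple[float, float, float, float]  # x, y, w, h in px
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2.0, y + h / 2.0)


@dataclass(frozen=True)
class ViewGroup:
    """One hypothesised animal at one tick: >= 2 single-camera detections."""

    tick: int
    members: tuple[Detection2D, ...]


@dataclass(frozen=True)
class VideoPoint:
    """Triangulated body position at one tick."""

    tick: int
    position: np.ndarray
    residual_px: float
    n_views: int
    in_cage: bool = True


def bucket_ticks(
    detections: list[Detection2D],
    tick_rate: float = 7.4,
    sync_tol: float | None = None,
) -> tuple[dict[int, list[Detection2D]], int]:
    """Assign detections to nearest tick centres; drop badly synced ones.

    Tick k covers time k / tick_rate.  Detections farther than ``sync_tol``
    (default: half a tick) from the nearest centre are dropped; the count of
    dropped detections is returned alongside the buckets.
    """
    if sync_tol is None:
        sync_tol = 0.5 / tick_rate
    buckets: dict[int, list[Detection2D]] = defaultdict(list)
    dropped = 0
    for det in detections:
        tick = int(round(det.timestamp * tick_rate))
        if abs(det.timestamp - tick / tick_rate) > sync_tol:
            dropped += 1
            continue
        buckets[tick].append(det)
    return dict(buckets), dropped


def _group_residual(
    members: list[Detection2D], tick: int, cameras: dict[str, CameraModel]
):
    cams = [cameras[d.camera_id] for d in members]
    pixels = np.array([d.center for d in members])
    return triangulate_pixels(cams, pixels, reject_outlier_views=False)


def _reproj_error(cam: CameraModel, pixel, point: np.ndarray) -> float:
    camf = cam.rotation @ point + cam.translation
    if camf[2] <= 0:
        return np.inf
    fx, fy = cam.focal
    cx, cy = cam.principal_point
    du = fx * camf[0] / camf[2] + cx - pixel[0]
    dv = fy * camf[1] / camf[2] + cy - pixel[1]
    return float(np.hypot(du, dv))


def associate_views(
    tick_detections: list[Detection2D],
    tick: int,
    cameras: dict[str, CameraModel],
    max_residual: float = 15.0,
    exhaustive: bool = False,
    cage: CageModel | None = None,
    cage_tol: float = 100.0,
) -> list[ViewGroup]:
    """Group same-tick body detections across cameras by triangulation residual.

    Default strategy: every cross-camera detection pair seeds a hypothesis;
    each hypothesis greedily absorbs the best-fitting detection from every
    other camera; hypotheses are then accepted in order of residual, each
    detection used at most once, and groups above ``max_residual`` rejected.
    When a ``cage`` is given, hypotheses triangulating outside the cage
    volume are discarded outright: two rays from *different* animals can
    intersect cleanly (a ghost point), but almost always far outside the
    box the animals actually live in.  ``exhaustive=True`` scores all joint
    camera assignments instead (small scenes only) and is used as an oracle
    in testing.
    """
    bodies = [d for d in tick_detections if d.det_class == "body"]
    per_cam: dict[str, list[Detection2D]] = defaultdict(list)
    for d in bodies:
        if d.camera_id in cameras:
            per_cam[d.camera_id].append(d)
    cam_ids = sorted(per_cam)
    if len(cam_ids) < 2:
        return []

    def in_volume(point):
        return cage is None or bool(cage.contains(point, tol=cage_tol))

    if exhaustive:
        return _associate_exhaustive(
            per_cam, cam_ids, tick, cameras, max_residual, in_volume
        )

    hypotheses = []  # (residual, members)
    for ca, cb in itertools.combinations(cam_ids, 2):
        for da, db in itertools.product(per_cam[ca], per_cam[cb]):
            members = [da, db]
            res = _group_residual(members, tick, cameras)
            if res.residual_px > max_residual or res.low_confidence:
                continue
            if not in_volume(res.point):
                continue
            # extend with the best-reprojecting detection from each remaining
            # camera (cheap check against the pair hypothesis point)
            for cc in cam_ids:
                if cc in (ca, cb):
                    continue
                best = None
                for dc in per_cam[cc]:
                    err = _reproj_error(cameras[cc], dc.center, res.point)
                    if err <= 2.0 * max_residual and (best is None or err < best[0]):
                        best = (err, dc)
                if best is not None:
                    members.append(best[1])
            final = _group_residual(members, tick, cameras)
            if final.residual_px <= max_residual and in_volume(final.point):
                hypotheses.append((final.residual_px, members))

    hypotheses.sort(key=lambda h: (h[0], -len(h[1])))
    used: set[int] = set()
    groups = []
    for resid, members in hypotheses:
        ids = {id(m) for m in members}
        if ids & used:
            continue
        used |= ids
        groups.append(ViewGroup(tick=tick, members=tuple(members)))
    return groups


def _associate_exhaustive(
    per_cam, cam_ids, tick, cameras, max_residual, in_volume=lambda p: True
):
    """Score every joint assignment of detections to animal slots (oracle)."""
    n_slots = max(len(v) for v in per_cam.values())
    if n_slots > 4:
        raise ValueError("exhaustive association supports at most 4 animals")

    def cam_assignments(dets):
        # injective maps detection -> slot, padded with None
        slots = list(range(n_slots))
        for perm in itertools.permutations(slots, len(dets)):
            yield dict(zip(perm, dets))

    best_score, best_groups = np.inf, []
    for combo in itertools.product(*(cam_assignments(per_cam[c]) for c in cam_ids)):
        slot_members: dict[int, list[Detection2D]] = defaultdict(list)
        for assignment in combo:
            for slot, det in assignment.items():
                slot_members[slot].append(det)
        score, groups, ok = 0.0, [], True
        for slot, members in slot_members.items():
            if len(members) < 2:
                ok = False
                break
            res = _group_residual(members, tick, cameras)
            if res.residual_px > max_residual or not in_volume(res.point):
                ok = False
                break
            score += res.residual_px
        if ok and slot_members and score < best_score:
            best_score = score
            best_groups = [
                ViewGroup(tick=tick, members=tuple(m))
                for m in slot_members.values()
            ]
    return best_groups


def localize_bodies(
    groups: list[ViewGroup],
    cameras: dict[str, CameraModel],
    cage: CageModel | None = None,
    cage_tol: float = 100.0,
) -> list[VideoPoint]:
    """Triangulate each view group's bbox centres into a 3D video point.

    Points landing outside the cage box (beyond ``cage_tol`` mm) are kept
    but flagged ``in_cage=False`` so downstream masking can treat them as
    missing.
    """
    points = []
    for group in groups:
        obs = [
            PixelObservation(d.camera_id, d.center, d.timestamp)
            for d in group.members
        ]
        try:
            res = triangulate(obs, cameras)
        except ValueError:
            continue
        in_cage = True
        if cage is not None:
            in_cage = bool(cage.contains(res.point, tol=cage_tol))
        points.append(
            VideoPoint(
                tick=group.tick,
                position=res.point,
                residual_px=res.residual_px,
                n_views=res.n_views,
                in_cage=in_cage,
            )
        )
    return points


def run_video_pipeline(
    detections: list[Detection2D],
    cameras: dict[str, CameraModel],
    cage: CageModel | None = None,
    tick_rate: float = 7.4,
    sync_tol: float | None = None,
    max_residual: float = 15.0,
) -> dict[int, list[VideoPoint]]:
    """Detections -> per-tick 3D video points."""
    buckets, _ = bucket_ticks(detections, tick_rate, sync_tol)
    out: dict[int, list[VideoPoint]] = {}
    for tick in sorted(buckets):
        groups = associate_views(buckets[tick], tick, cameras, max_residual, cage=cage)
        pts = localize_bodies(groups, cameras, cage)
        if pts:
            out[tick] = pts
    return out
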