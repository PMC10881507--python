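"""End-to-end pipeline: sensor streams in, identified behavior analytics out.

Stage order mirrors the acquisition design: video triangulation first
(primary positions), lidar clustering second (fallback positions), fusion
into anonymous tracklets, cage masking, identity linking from face events,
grooming-bout extraction, and finally trajectory analytics.  Each stage is
an ordinary library function; this module only sequences them and writes a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analytics, behavior, fusion, identity, lidar, video
from .config import PipelineConfig
from .geometry import default_camera_rig
from .simulator import GroundTruthScene


class MissingStreamError(RuntimeError):
    """A required input stream is absent; the message names the stage."""


@dataclass
class PipelineResult:
    tracklets: list[fusion.FusedTracklet]
    trajectories: list[identity.IdentifiedTrajectory]
    bouts: list[behavior.GroomingBout]
    occupancy: list[analytics.OccupancySummary]
    distances: "object"
    stats: dict
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    detections: list[video.Detection2D],
    clouds: list[lidar.PointCloud] | None = None,
    face_events: list[identity.FaceObservation] | None = None,
    grooming: dict[str, behavior.DetectionSeries] | None = None,
    background_scans: list[lidar.PointCloud] | None = None,
    cameras: dict | None = None,
) -> PipelineResult:
    """Run all stages on the given streams.

    ``detections`` is required (video is the primary modality); the lidar,
    face and grooming streams are optional and their stages are skipped
    when absent.
    """
    t_start = time.time()
    if not detections:
        raise MissingStreamError("video stage: no detections provided")
    cage = config.cage.build()
    if cameras is None:
        cameras = default_camera_rig(
            cage,
            standoff=config.rig.standoff,
            heights=config.rig.heights,
            spread=config.rig.spread,
            focal=config.rig.focal,
            image_size=config.rig.image_size,
        )

    video_points = video.run_video_pipeline(
        detections,
        cameras,
        cage,
        tick_rate=config.tick_rate,
        max_residual=config.max_residual,
    )

    lidar_tracks: list[lidar.LidarTrack] = []
    if clouds:
        if background_scans:
            bg = lidar.build_background(background_scans, config.cluster.voxel_size)
        else:
            bg = lidar.BackgroundModel(config.cluster.voxel_size, set())
        lidar_tracks = lidar.run_lidar_pipeline(
            clouds,
            bg,
            config.cluster.build(),
            gate=config.cluster.gate,
            dropout_window=config.cluster.dropout_window,
        )

    tracklets = fusion.fuse(
        video_points,
        lidar_tracks,
        config.fusion.build(),
        tick_rate=config.tick_rate,
    )
    tracklets = [fusion.apply_cage_mask(tr, cage) for tr in tracklets]
    stats = fusion.tracklet_stats(tracklets, config.tick_rate)

    if face_events:
        trajectories = identity.link_identities(
            tracklets,
            face_events,
            tick_rate=config.tick_rate,
            match_gate=config.identity.match_gate,
            min_confidence=config.identity.min_confidence,
            vote=config.identity.vote,
        )
    else:
        trajectories = [
            identity.IdentifiedTrajectory(None, list(tr.frames), [tr.tracklet_id])
            for tr in tracklets
        ]

    bouts: list[behavior.GroomingBout] = []
    if grooming:
        p = config.smooth.build()
        series = [behavior.smooth_series(s, p) for s in grooming.values()]
        combined = series[0]
        for s in series[1:]:
            combined = behavior.combine_cameras(combined, s)
        bouts = behavior.extract_bouts(combined, p.threshold)
        named = [tr for tr in trajectories if tr.individual_id is not None]
        attributed = []
        for b in bouts:
            loc = _bout_location(b, named, config.tick_rate)
            if loc is None:
                attributed.append(b)
            else:
                attributed.append(
                    behavior.attribute_bout(b, named, loc, config.tick_rate)
                )
        bouts = attributed

    zones = (
        [analytics.Zone(z.name, z.lo, z.hi) for z in config.zones]
        if config.zones
        else analytics.default_zones(cage)
    )
    named = [tr for tr in trajectories if tr.individual_id is not None]
    occupancy = [analytics.zone_occupancy(tr, zones) for tr in named]
    distances = analytics.pairwise_distances(named) if len(named) >= 2 else None

    manifest = {
        "config": config.model_dump(),
        "n_detections": len(detections),
        "n_clouds": len(clouds) if clouds else 0,
        "n_face_events": len(face_events) if face_events else 0,
        "runtime_s": round(time.time() - t_start, 3),
        "stats": stats,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()

    return PipelineResult(
        tracklets=tracklets,
        trajectories=trajectories,
        bouts=bouts,
        occupancy=occupancy,
        distances=distances,
        stats=stats,
        manifest=manifest,
    )


def _bout_location(bout, trajectories, tick_rate):
    """Midpoint of the nearest pair of animals during the bout interval."""
    k0 = int(np.floor(bout.start * tick_rate))
    k1 = int(np.ceil(bout.end * tick_rate))
    centers = []
    for tr in trajectories:
        pts = [
            fr.position
            for fr in tr.frames
            if fr.position is not None and k0 <= fr.tick <= k1
        ]
        if pts:
            centers.append(np.median(np.asarray(pts), axis=0))
    if len(centers) < 2:
        return centers[0] if centers else None
    best = None
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if best is None or d < best[0]:
                best = (d, (centers[i] + centers[j]) / 2.0)
    return best[1]


def run_on_scene(scene: GroundTruthScene, config: PipelineConfig | None = None) -> PipelineResult:
    """Convenience: run the full pipeline on a simulated scene's streams."""
    config = config or PipelineConfig(tick_rate=scene.tick_rate)
    return run_pipeline(
        config,
        detections=scene.sensors.detections,
        clouds=scene.sensors.clouds,
        face_events=scene.sensors.face_events,
        grooming=scene.sensors.grooming,
        cameras=scene.cameras,
    )
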