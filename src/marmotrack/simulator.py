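"""Ground-truth scene simulator and synthetic sensor rendering.

No public recordings exist for this kind of home-cage rig, so every
pipeline stage is exercised against simulated scenes with known ground
truth.  The simulator produces:

* true per-tick 3D trajectories for a small group of agents moving through
  the cage with a waypoint dwell/locomote/jump state machine, plus scripted
  social events (huddles, grooming bouts at fixed locations, excursions
  into a connected cage) that override free motion;
* synthetic sensor streams derived from the truth — per-camera bounding-box
  detections with pixel noise, speed/occlusion-dependent misses and false
  positives; lidar point clouds as Gaussian body blobs plus marmoset-tail
  false clusters; intermittent face-classification events drawn from a
  confusion-matrix surrogate classifier; and per-camera grooming-detection
  indicator series.

The motion model is waypoint-based, not biomechanical: it is meant to
reproduce the phenomena that stress the pipeline (fast jumps, huddles that
merge detections, fixed grooming spots, off-volume excursions), not
realistic marmoset gait.  Identical configuration and seed give
bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import BehindCameraError, CageModel, CameraModel, default_camera_rig
from .lidar import PointCloud
from .video import Detection2D
from .identity import UNKNOWN, FaceObservation
from .behavior import DetectionSeries


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentSpec:
    """One simulated animal.

    Speeds are documented guesses at marmoset scale: rest is stationary,
    locomotion up to 500 mm/s, jumps up to 3000 mm/s.
    """

    individual_id: str
    speed_range: tuple[float, float] = (100.0, 500.0)
    jump_speed: float = 3000.0
    state_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # rest/locomote/jump
    dwell_range: tuple[float, float] = (2.0, 12.0)
    home_zone: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if min(self.speed_range) < 0 or self.jump_speed < 0:
            raise ValueError("speeds must be non-negative")
        if abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValueError("state probabilities must sum to 1")


@dataclass(frozen=True)
class HuddleEvent:
    start: float
    duration: float
    participants: tuple[str, ...]
    location: tuple[float, float, float]


@dataclass(frozen=True)
class GroomEvent:
    start: float
    duration: float
    actor: str
    recipient: str
    location: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.actor == self.recipient:
            raise ValueError("groom actor and recipient must differ")

    @property
    def participants(self) -> tuple[str, str]:
        return (self.actor, self.recipient)


@dataclass(frozen=True)
class ExcursionEvent:
    """Off-volume interval: the agent leaves into a connected cage."""

    start: float
    duration: float
    agent: str


@dataclass(frozen=True)
class OcclusionEvent:
    """Window in which cameras cannot see the agent (miss probability 1)."""

    start: float
    duration: float
    agent: str | None = None  # None -> all agents


@dataclass(frozen=True)
class BehaviorScript:
    huddles: tuple[HuddleEvent, ...] = ()
    grooms: tuple[GroomEvent, ...] = ()
    excursions: tuple[ExcursionEvent, ...] = ()
    occlusions: tuple[OcclusionEvent, ...] = ()

    def exclusive_events_for(self, agent_id: str):
        evs = [e for e in self.huddles if agent_id in e.participants]
        evs += [e for e in self.grooms if agent_id in e.participants]
        evs += [e for e in self.excursions if e.agent == agent_id]
        return sorted(evs, key=lambda e: e.start)

    def validate(self, agent_ids: list[str], horizon: float) -> None:
        for e in (*self.huddles, *self.grooms, *self.excursions, *self.occlusions):
            if e.start < 0 or e.start + e.duration > horizon:
                raise ValueError("scripted event outside the simulation horizon")
        for aid in agent_ids:
            evs = self.exclusive_events_for(aid)
            for a, b in zip(evs, evs[1:]):
                if a.start + a.duration > b.start:
                    raise ValueError(
                        f"overlapping exclusive events for agent {aid!r}"
                    )


# ---------------------------------------------------------------------------
# Sensor specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraSensorSpec:
    tick_rate: float = 7.4
    pixel_noise: float = 1.0
    base_miss: float = 0.05
    speed_miss: float = 0.5  # extra miss probability at jump speed
    fp_rate: float = 0.01    # false positives per camera per tick
    body_size_mm: float = 180.0


@dataclass(frozen=True)
class LidarSensorSpec:
    scan_rate: float = 7.4
    point_noise: float = 10.0
    points_per_animal: int = 80
    blob_axes: tuple[float, float, float] = (60.0, 40.0, 40.0)
    tail_rate: float = 0.05       # tail false-cluster probability per animal-tick
    tail_points: int = 30
    tail_sigma: float = 22.0
    tail_offset: float = 350.0


@dataclass(frozen=True)
class FaceSensorSpec:
    rate: float = 0.2        # observations per second when the face is visible
    accuracy: float = 0.98   # probability the surrogate classifier is correct
    unknown_rate: float = 0.10
    position_noise: float = 20.0


@dataclass(frozen=True)
class GroomSensorSpec:
    hit_rate: float = 0.8     # per-frame detection probability during grooming
    false_alarm: float = 0.02


@dataclass(frozen=True)
class SensorSpec:
    camera: CameraSensorSpec = field(default_factory=CameraSensorSpec)
    lidar: LidarSensorSpec = field(default_factory=LidarSensorSpec)
    face: FaceSensorSpec = field(default_factory=FaceSensorSpec)
    groom: GroomSensorSpec = field(default_factory=GroomSensorSpec)


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

_MARGIN = 80.0  # keep agents off the cage walls, mm


def _active_event(events, t: float):
    for e in events:
        if e.start <= t < e.start + e.duration:
            return e
    return None


def simulate_trajectories(
    agents: list[AgentSpec],
    script: BehaviorScript,
    cage: CageModel,
    tick_rate: float = 7.4,
    horizon: float = 60.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """True per-tick positions per agent; NaN rows mark off-volume ticks.

    Free motion is a three-state machine (rest / locomote toward a waypoint
    / jump toward a waypoint) with dwell times drawn per state.  During a
    huddle or grooming event the participants converge to within 100 mm of
    the event location and stay there; during an excursion the agent is off
    volume.
    """
    ids = [a.individual_id for a in agents]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate agent ids")
    script.validate(ids, horizon)

    n_ticks = int(round(horizon * tick_rate))
    dt = 1.0 / tick_rate
    rngs = {a.individual_id: np.random.default_rng([seed, i]) for i, a in enumerate(agents)}
    out: dict[str, np.ndarray] = {}

    for agent in agents:
        rng = rngs[agent.individual_id]
        lo = np.array(agent.home_zone[0]) if agent.home_zone else np.full(3, _MARGIN)
        hi = (
            np.array(agent.home_zone[1])
            if agent.home_zone
            else np.array([cage.width, cage.depth, cage.height]) - _MARGIN
        )
        events = script.exclusive_events_for(agent.individual_id)

        pos = rng.uniform(lo, hi)
        waypoint = rng.uniform(lo, hi)
        state = 0
        state_left = float(rng.uniform(*agent.dwell_range))
        speed = 0.0
        # fixed per-agent offset keeps huddled animals distinct but within 100 mm
        event_offset = rng.normal(0, 30, size=3)
        event_offset *= min(1.0, 80.0 / max(np.linalg.norm(event_offset), 1e-9))

        traj = np.empty((n_ticks, 3))
        for k in range(n_ticks):
            t = k * dt
            ev = _active_event(events, t)
            if isinstance(ev, ExcursionEvent):
                traj[k] = np.nan
                continue
            if ev is not None:  # huddle or groom: converge to the event spot
                target = np.asarray(ev.location, dtype=float) + event_offset
                step = target - pos
                dist = np.linalg.norm(step)
                max_step = agent.jump_speed * dt
                pos = target if dist <= max_step else pos + step / dist * max_step
                traj[k] = pos
                continue

            state_left -= dt
            if state_left <= 0:
                state = int(rng.choice(3, p=agent.state_probs))
                state_left = float(rng.uniform(*agent.dwell_range))
                waypoint = rng.uniform(lo, hi)
                speed = (
                    0.0
                    if state == 0
                    else float(rng.uniform(*agent.speed_range))
                    if state == 1
                    else float(rng.uniform(0.6, 1.0) * agent.jump_speed)
                )
            if state != 0:
                step = waypoint - pos
                dist = np.linalg.norm(step)
                max_step = speed * dt
                if dist <= max_step:
                    pos = waypoint
                    state = 0  # arrived: rest until the next state draw
                else:
                    pos = pos + step / dist * max_step
            traj[k] = pos
        out[agent.individual_id] = traj
    return out


# ---------------------------------------------------------------------------
# Sensor rendering
# ---------------------------------------------------------------------------


@dataclass
class SensorStreams:
    detections: list[Detection2D]
    detection_truth: list[str | None]  # agent id per detection, None = false positive
    clouds: list[PointCloud]
    face_events: list[FaceObservation]
    face_truth: list[str]
    grooming: dict[str, DetectionSeries]


def _speeds(traj: np.ndarray, tick_rate: float) -> np.ndarray:
    v = np.zeros(len(traj))
    d = np.linalg.norm(np.diff(traj, axis=0), axis=1) * tick_rate
    v[1:] = d
    return np.nan_to_num(v)


def _occluded(script: BehaviorScript, agent_id: str, t: float) -> bool:
    for oc in script.occlusions:
        if (oc.agent is None or oc.agent == agent_id) and oc.start <= t < oc.start + oc.duration:
            return True
    return False


def _in_huddle(script: BehaviorScript, agent_id: str, t: float) -> bool:
    for e in script.huddles:
        if agent_id in e.participants and e.start <= t < e.start + e.duration:
            return True
    return False


def render_sensors(
    truth: dict[str, np.ndarray],
    cameras: dict[str, CameraModel],
    spec: SensorSpec,
    script: BehaviorScript,
    agents: list[AgentSpec],
    seed: int = 0,
) -> SensorStreams:
    """Render all synthetic sensor streams from a true scene."""
    tick_rate = spec.camera.tick_rate
    dt = 1.0 / tick_rate
    ids = list(truth)
    n_ticks = len(next(iter(truth.values())))
    speeds = {aid: _speeds(truth[aid], tick_rate) for aid in ids}
    jump_speed = {a.individual_id: a.jump_speed for a in agents}

    rng_cam = np.random.default_rng([seed, 101])
    rng_lid = np.random.default_rng([seed, 102])
    rng_face = np.random.default_rng([seed, 103])
    rng_groom = np.random.default_rng([seed, 104])

    detections: list[Detection2D] = []
    det_truth: list[str | None] = []
    for cam_id in sorted(cameras):
        cam = cameras[cam_id]
        w, h = cam.image_size
        for k in range(n_ticks):
            t = k * dt
            for aid in ids:
                p = truth[aid][k]
                if np.any(np.isnan(p)):
                    continue
                if _occluded(script, aid, t):
                    continue
                p_miss = spec.camera.base_miss + spec.camera.speed_miss * min(
                    speeds[aid][k] / max(jump_speed[aid], 1.0), 1.0
                )
                if rng_cam.uniform() < p_miss:
                    continue
                try:
                    uv = cam.project(p)
                except BehindCameraError:
                    continue
                depth = cam.to_camera_frame(p)[0, 2]
                size_px = cam.focal[0] * spec.camera.body_size_mm / depth
                uv = uv + rng_cam.normal(0, spec.camera.pixel_noise, size=2)
                if not (0 <= uv[0] < w and 0 <= uv[1] < h):
                    continue
                x = min(max(uv[0] - size_px / 2, 0.0), w - size_px)
                y = min(max(uv[1] - size_px / 2, 0.0), h - size_px)
                detections.append(
                    Detection2D(cam_id, t, "body", (x, y, size_px, size_px), 0.9)
                )
                det_truth.append(aid)
            n_fp = rng_cam.poisson(spec.camera.fp_rate)
            for _ in range(n_fp):
                size_px = 90.0
                x = rng_cam.uniform(0, w - size_px)
                y = rng_cam.uniform(0, h - size_px)
                detections.append(
                    Detection2D(cam_id, t, "body", (x, y, size_px, size_px), 0.4)
                )
                det_truth.append(None)

    clouds: list[PointCloud] = []
    lidar_dt = 1.0 / spec.lidar.scan_rate
    n_scans = int(round(n_ticks * dt / lidar_dt))
    for k in range(n_scans):
        t = k * lidar_dt
        tick = min(int(round(t * tick_rate)), n_ticks - 1)
        pts = []
        for aid in ids:
            p = truth[aid][tick]
            if np.any(np.isnan(p)):
                continue
            blob = rng_lid.normal(
                p, np.asarray(spec.lidar.blob_axes), size=(spec.lidar.points_per_animal, 3)
            )
            blob += rng_lid.normal(0, spec.lidar.point_noise, size=blob.shape)
            pts.append(blob)
            if rng_lid.uniform() < spec.lidar.tail_rate:
                ang = rng_lid.uniform(0, 2 * np.pi)
                off = np.array(
                    [np.cos(ang), np.sin(ang), 0.0]
                ) * spec.lidar.tail_offset
                tail = rng_lid.normal(
                    p + off, spec.lidar.tail_sigma, size=(spec.lidar.tail_points, 3)
                )
                pts.append(tail)
        clouds.append(
            PointCloud(t, np.vstack(pts) if pts else np.zeros((0, 3)))
        )

    face_events: list[FaceObservation] = []
    face_truth: list[str] = []
    p_obs = spec.face.rate * dt
    others = {aid: [b for b in ids if b != aid] for aid in ids}
    for k in range(n_ticks):
        t = k * dt
        for aid in ids:
            p = truth[aid][k]
            if np.any(np.isnan(p)):
                continue
            if _occluded(script, aid, t) or _in_huddle(script, aid, t):
                continue  # faces are hidden while huddled or occluded
            if rng_face.uniform() >= p_obs:
                continue
            u = rng_face.uniform()
            if u < spec.face.unknown_rate:
                pred = UNKNOWN
            elif rng_face.uniform() < spec.face.accuracy or not others[aid]:
                pred = aid
            else:
                pred = others[aid][rng_face.integers(len(others[aid]))]
            face_events.append(
                FaceObservation(
                    timestamp=t,
                    position=p + rng_face.normal(0, spec.face.position_noise, size=3),
                    predicted_id=pred,
                    confidence=float(rng_face.uniform(0.7, 1.0)),
                )
            )
            face_truth.append(aid)

    grooming: dict[str, DetectionSeries] = {}
    times = np.arange(n_ticks) * dt
    groom_active = np.zeros(n_ticks, dtype=bool)
    for e in script.grooms:
        k0 = int(np.floor(e.start * tick_rate))
        k1 = int(np.ceil((e.start + e.duration) * tick_rate))
        groom_active[k0 : min(k1, n_ticks)] = True
    for cam_id in sorted(cameras)[:2]:  # the two upper front cameras
        hits = np.where(
            groom_active,
            rng_groom.uniform(size=n_ticks) < spec.groom.hit_rate,
            rng_groom.uniform(size=n_ticks) < spec.groom.false_alarm,
        ).astype(float)
        grooming[cam_id] = DetectionSeries(cam_id, times, hits)

    return SensorStreams(
        detections=detections,
        detection_truth=det_truth,
        clouds=clouds,
        face_events=face_events,
        face_truth=face_truth,
        grooming=grooming,
    )


# ---------------------------------------------------------------------------
# Whole scenes and on-disk fixtures
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthScene:
    cage: CageModel
    cameras: dict[str, CameraModel]
    agents: list[AgentSpec]
    script: BehaviorScript
    tick_rate: float
    horizon: float
    seed: int
    trajectories: dict[str, np.ndarray]
    sensors: SensorStreams

    @property
    def ticks(self) -> np.ndarray:
        return np.arange(len(next(iter(self.trajectories.values()))))


def simulate_scene(
    agents: list[AgentSpec],
    script: BehaviorScript = BehaviorScript(),
    cage: CageModel | None = None,
    cameras: dict[str, CameraModel] | None = None,
    sensor_spec: SensorSpec = SensorSpec(),
    horizon: float = 60.0,
    seed: int = 0,
) -> GroundTruthScene:
    """Simulate truth and render all sensor streams in one call."""
    cage = cage or CageModel()
    cameras = cameras or default_camera_rig(cage)
    tick_rate = sensor_spec.camera.tick_rate
    truth = simulate_trajectories(agents, script, cage, tick_rate, horizon, seed)
    sensors = render_sensors(truth, cameras, sensor_spec, script, agents, seed)
    return GroundTruthScene(
        cage=cage,
        cameras=cameras,
        agents=agents,
        script=script,
        tick_rate=tick_rate,
        horizon=horizon,
        seed=seed,
        trajectories=truth,
        sensors=sensors,
    )


def truth_tick_maps(
    trajectories: dict[str, np.ndarray],
) -> dict[str, dict[int, np.ndarray]]:
    """True trajectories as per-individual {tick: position} maps (NaN dropped)."""
    out: dict[str, dict[int, np.ndarray]] = {}
    for aid, traj in trajectories.items():
        out[aid] = {
            k: traj[k] for k in range(len(traj)) if not np.any(np.isnan(traj[k]))
        }
    return out


def family3_agents() -> list[AgentSpec]:
    """Three-animal family: a floor-dwelling adult and two active animals."""
    return [
        AgentSpec("A", home_zone=((80, 80, 80), (740, 530, 400))),
        AgentSpec("B"),
        AgentSpec("C"),
    ]


def family3_script(horizon: float) -> BehaviorScript:
    """Grooming at two fixed upper locations plus one family huddle."""
    upper1 = (250.0, 300.0, 1250.0)
    upper2 = (600.0, 300.0, 1250.0)
    events = []
    t = 60.0
    toggle = True
    while t + 45.0 < horizon * 0.9:
        loc = upper1 if toggle else upper2
        events.append(GroomEvent(start=t, duration=40.0, actor="B", recipient="C", location=loc))
        toggle = not toggle
        t += max(150.0, horizon / 4)
    huddles = ()
    if horizon >= 500.0:
        huddles = (
            HuddleEvent(
                start=horizon * 0.55,
                duration=30.0,
                participants=("A", "B", "C"),
                location=(410.0, 300.0, 1300.0),
            ),
        )
    return BehaviorScript(grooms=tuple(events), huddles=huddles)


_PRESETS = {
    "family3": "three-agent family scene with scripted grooming bouts",
    "crossing": "two agents repeatedly crossing paths",
    "huddle": "three agents with a long huddle (ID-switch stress test)",
}


def preset_scene(name: str, horizon: float = 120.0, seed: int = 0) -> GroundTruthScene:
    if name == "family3":
        return simulate_scene(
            family3_agents(), family3_script(horizon), horizon=horizon, seed=seed
        )
    if name == "crossing":
        agents = [
            AgentSpec("A", home_zone=((80, 80, 80), (740, 530, 700)), state_probs=(0.1, 0.8, 0.1)),
            AgentSpec("B", home_zone=((80, 80, 80), (740, 530, 700)), state_probs=(0.1, 0.8, 0.1)),
        ]
        return simulate_scene(agents, BehaviorScript(), horizon=horizon, seed=seed)
    if name == "huddle":
        agents = family3_agents()
        script = BehaviorScript(
            huddles=(
                HuddleEvent(
                    start=horizon * 0.3,
                    duration=horizon * 0.3,
                    participants=("A", "B", "C"),
                    location=(410.0, 300.0, 1300.0),
                ),
            )
        )
        return simulate_scene(agents, script, horizon=horizon, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_fixture(name: str, out_dir: str | Path, horizon: float = 120.0, seed: int = 0) -> Path:
    """Write a preset scene bundle (truth + streams + manifest) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = preset_scene(name, horizon=horizon, seed=seed)

    rows = []
    for aid, traj in scene.trajectories.items():
        for k, p in enumerate(traj):
            rows.append((k, aid, *(("" if np.isnan(v) else v) for v in p)))
    pd.DataFrame(rows, columns=["tick", "id", "x", "y", "z"]).to_csv(
        out / "truth.csv", index=False
    )

    det = scene.sensors.detections
    pd.DataFrame(
        {
            "camera_id": [d.camera_id for d in det],
            "t": [d.timestamp for d in det],
            "class": [d.det_class for d in det],
            "x": [d.bbox[0] for d in det],
            "y": [d.bbox[1] for d in det],
            "w": [d.bbox[2] for d in det],
            "h": [d.bbox[3] for d in det],
            "conf": [d.confidence for d in det],
            "truth_agent": ["" if a is None else a for a in scene.sensors.detection_truth],
        }
    ).to_csv(out / "detections.csv", index=False)

    cloud_rows = []
    for cloud in scene.sensors.clouds:
        for p in cloud.points:
            cloud_rows.append((cloud.timestamp, *p))
    pd.DataFrame(cloud_rows, columns=["t", "x", "y", "z"]).to_csv(
        out / "clouds.csv", index=False
    )

    fe = scene.sensors.face_events
    pd.DataFrame(
        {
            "t": [o.timestamp for o in fe],
            "x": [o.position[0] for o in fe],
            "y": [o.position[1] for o in fe],
            "z": [o.position[2] for o in fe],
            "predicted_id": [o.predicted_id for o in fe],
            "confidence": [o.confidence for o in fe],
            "truth_agent": scene.sensors.face_truth,
        }
    ).to_csv(out / "face_events.csv", index=False)

    for cam_id, series in scene.sensors.grooming.items():
        pd.DataFrame({"t": series.times, "value": series.values}).to_csv(
            out / f"grooming_{cam_id}.csv", index=False
        )

    config = {
        "fixture": name,
        "horizon": horizon,
        "seed": seed,
        "tick_rate": scene.tick_rate,
        "cage": {"width": scene.cage.width, "depth": scene.cage.depth, "height": scene.cage.height},
        "agents": [a.individual_id for a in scene.agents],
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "fixture": name,
        "seed": seed,
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
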