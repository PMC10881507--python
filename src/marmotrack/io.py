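"""Columnar file formats: trajectories, detections, clouds, face events."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import DetectionSeries
from .fusion import Frame, SOURCE_MISSING
from .identity import FaceObservation, IdentifiedTrajectory
from .lidar import PointCloud
from .video import Detection2D

TRAJECTORY_COLUMNS = ["tick", "id", "x", "y", "z", "source"]


class MalformedRowError(ValueError):
    """A data file row failed to parse; the message names the line."""


def write_trajectories(trajs: list[IdentifiedTrajectory], path: str | Path) -> None:
    """Write identified trajectories as CSV; missing positions are empty fields."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRAJECTORY_COLUMNS)
        for traj in trajs:
            label = traj.individual_id if traj.individual_id is not None else ""
            for fr in traj.frames:
                if fr.position is None:
                    writer.writerow([fr.tick, label, "", "", "", fr.source])
                else:
                    writer.writerow(
                        [fr.tick, label, *(f"{v:.3f}" for v in fr.position), fr.source]
                    )


def read_trajectories(path: str | Path) -> list[IdentifiedTrajectory]:
    """Read a trajectory CSV back; malformed rows raise with the line number."""
    by_id: dict[str | None, IdentifiedTrajectory] = {}
    order: list[str | None] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != TRAJECTORY_COLUMNS:
            raise MalformedRowError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 6:
                raise MalformedRowError(f"{path}: line {lineno}: expected 6 fields")
            tick_s, label, xs, ys, zs, source = row
            try:
                tick = int(tick_s)
                coords = (xs, ys, zs)
                if any(c == "" for c in coords):
                    if not all(c == "" for c in coords):
                        raise ValueError("partially missing coordinates")
                    pos = None
                else:
                    pos = np.array([float(c) for c in coords])
            except ValueError as exc:
                raise MalformedRowError(f"{path}: line {lineno}: {exc}") from exc
            key = label or None
            if key not in by_id:
                by_id[key] = IdentifiedTrajectory(key, [])
                order.append(key)
            by_id[key].frames.append(Frame(tick, pos, source or SOURCE_MISSING))
    return [by_id[k] for k in order]


def read_detections(path: str | Path) -> list[Detection2D]:
    df = pd.read_csv(path)
    return [
        Detection2D(
            camera_id=str(cam),
            timestamp=float(t),
            det_class=str(cls),
            bbox=(float(x), float(y), float(w), float(h)),
            confidence=float(conf),
        )
        for cam, t, cls, x, y, w, h, conf in zip(
            df["camera_id"], df["t"], df["class"], df["x"], df["y"], df["w"],
            df["h"], df["conf"],
        )
    ]


def read_clouds(path: str | Path) -> list[PointCloud]:
    df = pd.read_csv(path)
    clouds = []
    for t, grp in df.groupby("t", sort=True):
        clouds.append(PointCloud(float(t), grp[["x", "y", "z"]].to_numpy()))
    return clouds


def read_face_events(path: str | Path) -> list[FaceObservation]:
    df = pd.read_csv(path)
    return [
        FaceObservation(
            timestamp=float(r.t),
            position=np.array([r.x, r.y, r.z], dtype=float),
            predicted_id=str(r.predicted_id),
            confidence=float(r.confidence),
        )
        for r in df.itertuples(index=False)
    ]


def read_grooming_series(path: str | Path, camera_id: str) -> DetectionSeries:
    df = pd.read_csv(path)
    return DetectionSeries(camera_id, df["t"].to_numpy(), df["value"].to_numpy())


def read_truth(path: str | Path) -> dict[str, dict[int, np.ndarray]]:
    """Ground-truth CSV (tick, id, x, y, z) -> per-individual tick maps."""
    df = pd.read_csv(path)
    out: dict[str, dict[int, np.ndarray]] = {}
    for r in df.itertuples(index=False):
        if pd.isna(r.x):
            continue
        out.setdefault(str(r.id), {})[int(r.tick)] = np.array(
            [r.x, r.y, r.z], dtype=float
        )
    return out
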