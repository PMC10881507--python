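"""Video-primary / lidar-fallback fusion into anonymous 3D tracklets.

Video triangulation is the primary position source: it is precise and
rarely fooled by marmoset-sized clutter, but loses the animal during fast
jumps or occlusion.  The lidar centroid stream rarely misses a moving body
but picks up false marmoset-sized clusters (tails, feeders, balls).  The
fusion rule therefore extends each live tracklet per tick with, in order:

1. the nearest unclaimed video point within the motion gate,
2. else the nearest unclaimed lidar centroid within the handoff gate of the
   last known position,
3. else a missing frame; after ``max_gap`` seconds of missing the tracklet
   closes.

Unclaimed *video* points open new tracklets (lidar alone never does, which
keeps lidar false clusters from seeding ghost tracks).  Every frame is
tagged with the modality that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import CageModel
from .lidar import LidarTrack

SOURCE_VIDEO = "video"
SOURCE_LIDAR = "lidar"
SOURCE_MISSING = "missing"


@dataclass(frozen=True)
class FusionParams:
    gate: float = 300.0         # max per-tick displacement, mm
    switch_gate: float = 200.0  # max video<->lidar handoff distance, mm
    max_gap: float = 1.0        # seconds of missing before tracklet break

    def __post_init__(self) -> None:
        if min(self.gate, self.switch_gate, self.max_gap) <= 0:
            raise ValueError("fusion parameters must be positive")


@dataclass(frozen=True)
class Frame:
    tick: int
    position: np.ndarray | None  # None when missing
    source: str
    masked_source: str | None = None  # original source for cage-masked frames


@dataclass
class FusedTracklet:
    tracklet_id: int
    frames: list[Frame] = field(default_factory=list)

    @property
    def start_tick(self) -> int:
        return self.frames[0].tick

    @property
    def end_tick(self) -> int:
        return self.frames[-1].tick

    def duration(self, tick_rate: float) -> float:
        return (self.end_tick - self.start_tick + 1) / tick_rate

    @property
    def last_known(self) -> tuple[int, np.ndarray] | None:
        for fr in reversed(self.frames):
            if fr.position is not None:
                return fr.tick, fr.position
        return None


def _match(
    last_positions: list[np.ndarray],
    candidates: list[np.ndarray],
    max_dist: list[float],
) -> dict[int, int]:
    """Global min-cost one-to-one matching; returns {candidate_i: row_i}."""
    if not last_positions or not candidates:
        return {}
    cost = np.array(
        [[np.linalg.norm(p - c) for c in candidates] for p in last_positions]
    )
    allowed = cost <= np.asarray(max_dist)[:, None]
    big = 1e9
    rows, cols = linear_sum_assignment(np.where(allowed, cost, big))
    return {c: r for r, c in zip(rows, cols) if allowed[r, c]}


def _lidar_by_tick(
    lidar_tracks: list[LidarTrack], tick_rate: float
) -> dict[int, list[np.ndarray]]:
    out: dict[int, list[np.ndarray]] = {}
    for tr in lidar_tracks:
        for t, c in tr.samples:
            tick = int(round(t * tick_rate))
            out.setdefault(tick, []).append(c)
    return out


def fuse(
    video_points: dict[int, list],
    lidar_tracks: list[LidarTrack],
    params: FusionParams = FusionParams(),
    tick_rate: float = 7.4,
    tick_range: tuple[int, int] | None = None,
) -> list[FusedTracklet]:
    """Merge per-tick video points with lidar tracks into fused tracklets.

    ``video_points`` maps tick -> list of objects with a ``position``
    attribute (``VideoPoint``) or raw 3D arrays.  Video points flagged
    out-of-cage are treated as absent.
    """
    lidar_by_tick = _lidar_by_tick(lidar_tracks, tick_rate)
    if tick_range is None:
        ticks = set(video_points) | set(lidar_by_tick)
        if not ticks:
            return []
        tick_range = (min(ticks), max(ticks))
    max_gap_ticks = int(np.ceil(params.max_gap * tick_rate))

    live: list[FusedTracklet] = []
    done: list[FusedTracklet] = []
    next_id = 0

    for tick in range(tick_range[0], tick_range[1] + 1):
        vids = []
        for vp in video_points.get(tick, []):
            pos = getattr(vp, "position", vp)
            if getattr(vp, "in_cage", True):
                vids.append(np.asarray(pos, dtype=float))
        lids = [np.asarray(c, dtype=float) for c in lidar_by_tick.get(tick, [])]

        # close tracklets whose gap exceeded max_gap
        still = []
        for tr in live:
            lk = tr.last_known
            if lk is not None and tick - lk[0] > max_gap_ticks:
                while tr.frames and tr.frames[-1].position is None:
                    tr.frames.pop()  # trim trailing missing frames
                done.append(tr)
            else:
                still.append(tr)
        live = still

        anchors, gates = [], []
        for tr in live:
            lk = tr.last_known
            anchors.append(lk[1])
            gates.append(params.gate * max(1, tick - lk[0]))

        claimed_tracklet: set[int] = set()
        extended: dict[int, tuple[np.ndarray, str]] = {}

        vid_match = _match(anchors, vids, gates)
        used_vids = set()
        for ci, ri in vid_match.items():
            extended[ri] = (vids[ci], SOURCE_VIDEO)
            claimed_tracklet.add(ri)
            used_vids.add(ci)

        # lidar fallback for tracklets the video missed, within switch gate
        free_rows = [i for i in range(len(live)) if i not in claimed_tracklet]
        lid_match = _match(
            [anchors[i] for i in free_rows],
            lids,
            [min(gates[i], params.switch_gate) for i in free_rows],
        )
        for ci, sub_r in lid_match.items():
            ri = free_rows[sub_r]
            extended[ri] = (lids[ci], SOURCE_LIDAR)
            claimed_tracklet.add(ri)

        for i, tr in enumerate(live):
            if i in extended:
                pos, src = extended[i]
                tr.frames.append(Frame(tick, pos, src))
            else:
                tr.frames.append(Frame(tick, None, SOURCE_MISSING))

        # unclaimed video points seed new tracklets
        for ci, pos in enumerate(vids):
            if ci in used_vids:
                continue
            tr = FusedTracklet(next_id, [Frame(tick, pos, SOURCE_VIDEO)])
            next_id += 1
            live.append(tr)

    for tr in live:
        while tr.frames and tr.frames[-1].position is None:
            tr.frames.pop()
        if tr.frames:
            done.append(tr)
    return sorted(done, key=lambda tr: tr.tracklet_id)


def apply_cage_mask(
    tracklet: FusedTracklet, cage: CageModel, tol: float = 50.0
) -> FusedTracklet:
    """Replace out-of-cage positions with missing values.

    Coordinates landing outside the cage volume (an excursion into a
    connected cage, or a bad triangulation) are not trustworthy animal
    positions; they become missing frames, with the producing modality
    preserved in ``masked_source`` for diagnostics.
    """
    frames = []
    for fr in tracklet.frames:
        if fr.position is not None and not cage.contains(fr.position, tol=tol):
            frames.append(Frame(fr.tick, None, SOURCE_MISSING, masked_source=fr.source))
        else:
            frames.append(fr)
    return FusedTracklet(tracklet.tracklet_id, frames)


def tracklet_stats(
    tracklets: list[FusedTracklet], tick_rate: float = 7.4
) -> dict[str, float]:
    """Count, mean duration (s) and per-modality source fractions."""
    n = len(tracklets)
    durations = [tr.duration(tick_rate) for tr in tracklets]
    counts = {SOURCE_VIDEO: 0, SOURCE_LIDAR: 0, SOURCE_MISSING: 0}
    total = 0
    for tr in tracklets:
        for fr in tr.frames:
            counts[fr.source] += 1
            total += 1
    fractions = {
        f"{src}_fraction": (c / total if total else 0.0) for src, c in counts.items()
    }
    return {
        "count": n,
        "mean_duration_s": float(np.mean(durations)) if durations else 0.0,
        **fractions,
    }
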