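"""Identity assignment and classification / ID-accuracy metrics.

Anonymous fused tracklets become identified trajectories through sparse,
intermittent face-classification events: whenever the classifier sees a
face it emits (time, 3D position, predicted individual, confidence).  Each
usable event attaches to the nearest tracklet position within a gate, and
each tracklet takes the (confidence-weighted) majority vote of its
attached events; ties leave the tracklet unidentified.  If two concurrent
tracklets claim the same individual, the one with the larger vote mass
keeps it.

The module also provides the standard one-vs-rest classification metrics
(specificity, accuracy, recall, precision, F-measure) used to score the
face classifier itself, and an ID-switch report scoring an identified
trajectory set against per-tick ground truth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .fusion import Frame, FusedTracklet

UNKNOWN = "unknown"


@dataclass(frozen=True)
class FaceObservation:
    timestamp: float
    position: np.ndarray
    predicted_id: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass
class IdentifiedTrajectory:
    individual_id: str | None
    frames: list[Frame] = field(default_factory=list)
    tracklet_ids: list[int] = field(default_factory=list)


def _tally(entries) -> tuple[str | None, float]:
    """Confidence-weighted majority; ties are unidentified."""
    weight: dict[str, float] = defaultdict(float)
    for _, pid, conf in entries:
        weight[pid] += conf
    if not weight:
        return None, 0.0
    ranked = sorted(weight.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None, ranked[0][1]
    return ranked[0]


def link_identities(
    tracklets: list[FusedTracklet],
    face_obs: list[FaceObservation],
    tick_rate: float = 7.4,
    match_gate: float = 200.0,
    min_confidence: float = 0.0,
    vote: str = "windowed",
    window_s: float = 60.0,
) -> list[IdentifiedTrajectory]:
    """Attach face events to tracklets and vote identities.

    ``vote="majority"`` gives every frame of a tracklet the
    confidence-weighted majority label of all its attached observations
    (ties -> unidentified).  ``vote="windowed"`` (default) is a sliding
    recency-weighted vote: each frame is labelled by the majority of the
    tracklet's observations with weights ``confidence *
    exp(-|t_obs - t_frame| / (window_s/8))``, so nearby-in-time
    observations dominate.  The windowed rule re-identifies a tracklet as
    soon as a face is seen again, so an identity swap inside a long
    tracklet (after a huddle or crossing) is corrected within a few
    observations rather than propagated to the end of the tracklet.
    Per tick, if two tracklets claim one individual the frame with the
    larger vote mass keeps it; the loser's frame goes unidentified.
    """
    if vote not in ("majority", "windowed"):
        raise ValueError(f"unknown vote rule {vote!r}")

    # index tracklet frames by tick for nearest-position attachment
    frames_at: dict[int, list[tuple[int, np.ndarray]]] = defaultdict(list)
    for ti, tr in enumerate(tracklets):
        for fr in tr.frames:
            if fr.position is not None:
                frames_at[fr.tick].append((ti, fr.position))

    votes: dict[int, list[tuple[float, str, float]]] = defaultdict(list)
    for obs in face_obs:
        if obs.predicted_id == UNKNOWN or obs.confidence < min_confidence:
            continue
        tick = int(round(obs.timestamp * tick_rate))
        best = None
        for dt in (0, -1, 1):  # tolerate one tick of clock skew
            for ti, pos in frames_at.get(tick + dt, []):
                d = float(np.linalg.norm(pos - obs.position))
                if d <= match_gate and (best is None or d < best[0]):
                    best = (d, ti)
            if best is not None:
                break
        if best is not None:
            votes[best[1]].append((obs.timestamp, obs.predicted_id, obs.confidence))

    # per-frame vote-mass vectors for each tracklet
    tau = window_s / 8.0  # recency time constant of the windowed vote
    frame_masses: dict[int, list[dict[str, float]]] = {}
    for ti, tr in enumerate(tracklets):
        entries = sorted(votes.get(ti, []))
        if vote == "majority" or not entries:
            whole: dict[str, float] = defaultdict(float)
            for _, pid, conf in entries:
                whole[pid] += conf
            frame_masses[ti] = [dict(whole)] * len(tr.frames)
            continue
        obs_t = np.array([e[0] for e in entries])
        obs_id = [e[1] for e in entries]
        obs_conf = np.array([e[2] for e in entries])
        uniq = sorted(set(obs_id))
        onehot = np.array([[pid == u for u in uniq] for pid in obs_id], dtype=float)
        frame_t = np.array([fr.tick for fr in tr.frames]) / tick_rate
        w = obs_conf[None, :] * np.exp(
            -np.abs(obs_t[None, :] - frame_t[:, None]) / tau
        )
        mass = w @ onehot  # (n_frames, n_ids)
        frame_masses[ti] = [
            {u: float(m) for u, m in zip(uniq, row) if m > 0} for row in mass
        ]

    # per tick, optimal one-to-one assignment of identities to frames
    # (maximum total vote mass); exact ties leave frames unidentified
    frames_by_tick: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for ti, tr in enumerate(tracklets):
        for fi, fr in enumerate(tr.frames):
            if frame_masses[ti][fi]:
                frames_by_tick[fr.tick].append((ti, fi))

    assigned: dict[tuple[int, int], str] = {}
    for tick, entries_t in frames_by_tick.items():
        ids = sorted({pid for ti, fi in entries_t for pid in frame_masses[ti][fi]})
        if len(entries_t) == 1 and len(ids) >= 1:
            ti, fi = entries_t[0]
            mass = frame_masses[ti][fi]
            ranked = sorted(mass.items(), key=lambda kv: -kv[1])
            if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                assigned[(ti, fi)] = ranked[0][0]
            continue
        cost = np.zeros((len(entries_t), len(ids)))
        for r, (ti, fi) in enumerate(entries_t):
            for c, pid in enumerate(ids):
                cost[r, c] = -frame_masses[ti][fi].get(pid, 0.0)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < 0:
                assigned[entries_t[r]] = ids[c]

    merged: dict[str, IdentifiedTrajectory] = {}
    out: list[IdentifiedTrajectory] = []
    for ti, tr in enumerate(tracklets):
        leftovers: list[Frame] = []
        for fi, fr in enumerate(tr.frames):
            pid = assigned.get((ti, fi))
            if pid is not None:
                if pid not in merged:
                    merged[pid] = IdentifiedTrajectory(pid, [], [])
                    out.append(merged[pid])
                merged[pid].frames.append(fr)
                if tr.tracklet_id not in merged[pid].tracklet_ids:
                    merged[pid].tracklet_ids.append(tr.tracklet_id)
            else:
                leftovers.append(fr)
        if leftovers:
            out.append(IdentifiedTrajectory(None, leftovers, [tr.tracklet_id]))
    for traj in out:
        traj.frames.sort(key=lambda fr: fr.tick)
    return out


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """Per-class one-vs-rest counts over a fixed evaluation set."""

    counts: dict[str, dict[str, int]]  # class -> {tp, fp, fn, tn}

    def __post_init__(self) -> None:
        totals = set()
        for cls, c in self.counts.items():
            if any(v < 0 for v in c.values()):
                raise ValueError(f"negative count for class {cls!r}")
            totals.add(c["tp"] + c["fp"] + c["fn"] + c["tn"])
        if len(totals) > 1:
            raise ValueError("one-vs-rest totals differ across classes")

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, class_names: list[str]) -> "ConfusionTable":
        """Build from a square confusion matrix (rows true, cols predicted)."""
        m = np.asarray(matrix, dtype=int)
        total = int(m.sum())
        counts = {}
        for i, name in enumerate(class_names):
            tp = int(m[i, i])
            fn = int(m[i].sum()) - tp
            fp = int(m[:, i].sum()) - tp
            counts[name] = {"tp": tp, "fp": fp, "fn": fn, "tn": total - tp - fn - fp}
        return cls(counts)


def _pct(x: float | None) -> float | None:
    """Round a percentage to one decimal, half away from zero."""
    if x is None:
        return None
    return float(np.floor(x * 10 + 0.5) / 10)


def f_measure(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, in percent (one decimal)."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return _pct(2 * precision_pct * recall_pct / (precision_pct + recall_pct))


def classification_metrics(
    confusion: ConfusionTable,
) -> dict[str, dict[str, float | None]]:
    """One-vs-rest specificity/accuracy/recall/precision/F per class (percent).

    Metrics with a zero denominator are reported as ``None`` (undefined)
    rather than forced to a number.
    """
    out = {}
    for cls, c in confusion.counts.items():
        tp, fp, fn, tn = c["tp"], c["fp"], c["fn"], c["tn"]

        def ratio(num, den):
            return 100.0 * num / den if den > 0 else None

        spec = ratio(tn, tn + fp)
        acc = ratio(tp + tn, tp + fp + fn + tn)
        rec = ratio(tp, tp + fn)
        prec = ratio(tp, tp + fp)
        if prec is None or rec is None or prec + rec == 0:
            f = None
        else:
            f = 2 * prec * rec / (prec + rec)
        out[cls] = {
            "specificity": _pct(spec),
            "accuracy": _pct(acc),
            "recall": _pct(rec),
            "precision": _pct(prec),
            "f_measure": _pct(f),
        }
    return out


def overall_accuracy(
    per_class_correct: dict[str, int] | list[int],
    per_class_total: dict[str, int] | list[int],
) -> float:
    """100 x (total correct / total images), one decimal."""
    if isinstance(per_class_correct, dict):
        keys = list(per_class_correct)
        correct = [per_class_correct[k] for k in keys]
        total = [per_class_total[k] for k in keys]
    else:
        correct, total = list(per_class_correct), list(per_class_total)
    denom = sum(total)
    if denom <= 0:
        raise ValueError("total image count must be positive")
    return _pct(100.0 * sum(correct) / denom)


# ---------------------------------------------------------------------------
# ID-switch accounting against ground truth
# ---------------------------------------------------------------------------


def _positions_by_tick(frames: list[Frame]) -> dict[int, np.ndarray]:
    return {fr.tick: fr.position for fr in frames if fr.position is not None}


def correct_id_fraction(
    estimated: list[IdentifiedTrajectory],
    truth: dict[str, dict[int, np.ndarray]],
    match_tol: float = 250.0,
) -> float:
    """Fraction of (individual, tick) truth samples carrying the right label.

    A truth sample counts as correctly identified when the trajectory
    labelled with that individual has a position at that tick within
    ``match_tol`` mm of the true position.  Ticks with no estimate, or an
    estimate that is nearer another animal's truth, count against.
    """
    est_pos = {
        tr.individual_id: _positions_by_tick(tr.frames)
        for tr in estimated
        if tr.individual_id is not None
    }
    total = 0
    correct = 0
    for tid, tt in truth.items():
        series = est_pos.get(tid, {})
        for tick, true_p in tt.items():
            total += 1
            p = series.get(tick)
            if p is not None and float(np.linalg.norm(p - true_p)) <= match_tol:
                correct += 1
    if total == 0:
        raise ValueError("ground truth is empty")
    return correct / total


def id_switch_report(
    estimated: list[IdentifiedTrajectory],
    truth: dict[str, dict[int, np.ndarray]],
    tick_rate: float = 7.4,
    min_duration: float = 5.0,
) -> dict[str, float]:
    """Count sustained wrong-ID runs against per-tick ground truth.

    At each tick where an identified trajectory has a position, the nearest
    true individual is found; the frame is wrong when that individual is
    not the trajectory's label.  Maximal wrong runs of at least
    ``min_duration`` seconds are counted as switches; ``wrong_id_fraction``
    is their summed duration over the record horizon, and
    ``max_correct_streak_s`` the longest continuously correct stretch.
    """
    all_ticks = sorted({t for tt in truth.values() for t in tt})
    if not all_ticks:
        raise ValueError("ground truth is empty")
    horizon_s = (all_ticks[-1] - all_ticks[0] + 1) / tick_rate
    min_run_ticks = int(np.ceil(min_duration * tick_rate))

    n_switches = 0
    wrong_time_s = 0.0
    max_correct = 0

    for traj in estimated:
        if traj.individual_id is None:
            continue
        series = []  # (tick, correct?)
        for tick, pos in sorted(_positions_by_tick(traj.frames).items()):
            best_id, best_d = None, np.inf
            for tid, tt in truth.items():
                if tick in tt:
                    d = float(np.linalg.norm(tt[tick] - pos))
                    if d < best_d:
                        best_id, best_d = tid, d
            if best_id is None:
                continue
            series.append((tick, best_id == traj.individual_id))

        run_len, run_correct = 0, None
        for i, (tick, correct) in enumerate(series):
            if run_correct is None or correct != run_correct:
                if run_correct is False and run_len >= min_run_ticks:
                    n_switches += 1
                    wrong_time_s += run_len / tick_rate
                if run_correct is True:
                    max_correct = max(max_correct, run_len)
                run_len, run_correct = 1, correct
            else:
                run_len += 1
        if run_correct is False and run_len >= min_run_ticks:
            n_switches += 1
            wrong_time_s += run_len / tick_rate
        if run_correct is True:
            max_correct = max(max_correct, run_len)

    return {
        "n_switches": n_switches,
        "wrong_id_fraction": wrong_time_s / horizon_s,
        "max_correct_streak_s": max_correct / tick_rate,
    }
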