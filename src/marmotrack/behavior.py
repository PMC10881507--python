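"""Grooming-bout detection and unit-level evaluation.

The behavior detector marks, for every analysed video frame of the two
upper front cameras, whether allogrooming is visible (a 0/1 indicator per
tick).  Raw per-frame indicators are noisy, so each camera's series is
smoothed with a Gaussian-weighted moving average over a 50-s window
evaluated every 5 s, the two cameras' smoothed series are averaged
pointwise, and maximal runs above a probability threshold become grooming
bouts.  A bout is attributed to the (at most two) individuals closest to
the grooming location during its interval, and detection quality is scored
against human annotation in 30-s units: a unit is positive for a source
when any of its bouts overlaps the unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DetectionSeries:
    """Uniform per-tick grooming-detection counts for one camera."""

    camera_id: str
    times: np.ndarray  # tick centre times, s
    values: np.ndarray  # detection count (0/1) per tick

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be equal-length 1D arrays")
        if t.size == 0:
            raise ValueError("empty detection series")
        if np.any(v < 0):
            raise ValueError("detection counts must be non-negative")
        if t.size > 1:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("tick grid must be uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SmoothParams:
    window: float = 50.0  # s
    slide: float = 5.0    # s
    sigma: float | None = None  # default window / 6
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.window > self.slide > 0:
            raise ValueError("window must exceed slide, both positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def sigma_eff(self) -> float:
        # window/6 puts ~99.7% of the Gaussian mass inside the window
        return self.sigma if self.sigma is not None else self.window / 6.0


@dataclass(frozen=True)
class ProbabilitySeries:
    """Smoothed grooming-occurrence probability on the slide grid."""

    times: np.ndarray
    values: np.ndarray
    slide: float


@dataclass(frozen=True)
class GroomingBout:
    start: float
    end: float
    location: np.ndarray | None = None
    participants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout must have positive duration")


def smooth_series(series: DetectionSeries, p: SmoothParams) -> ProbabilitySeries:
    """Gaussian-weighted moving average on the slide grid.

    Each output point is the normalised Gaussian-weighted mean of the
    per-tick detection frequency inside the centred window; edge windows
    are truncated and renormalised, so a constant input maps to the same
    constant.
    """
    t0, t1 = series.times[0], series.times[-1]
    grid = np.arange(t0, t1 + 1e-9, p.slide)
    half = p.window / 2.0
    sig = p.sigma_eff
    out = np.empty_like(grid)
    for i, tc in enumerate(grid):
        mask = np.abs(series.times - tc) <= half
        if not np.any(mask):
            out[i] = 0.0
            continue
        w = np.exp(-0.5 * ((series.times[mask] - tc) / sig) ** 2)
        out[i] = float(np.sum(w * series.values[mask]) / np.sum(w))
    return ProbabilitySeries(times=grid, values=out, slide=p.slide)


def combine_cameras(left: ProbabilitySeries, right: ProbabilitySeries) -> ProbabilitySeries:
    """Pointwise mean of the two cameras' smoothed series."""
    if left.slide != right.slide or left.times.shape != right.times.shape or not np.allclose(
        left.times, right.times
    ):
        raise ValueError("probability series are on different slide grids")
    return ProbabilitySeries(
        times=left.times, values=(left.values + right.values) / 2.0, slide=left.slide
    )


def extract_bouts(series: ProbabilitySeries, threshold: float = 0.5) -> list[GroomingBout]:
    """Maximal supra-threshold runs on the slide grid, as (start, end) bouts.

    A run of k consecutive grid points spans k x slide seconds (half a
    slide step beyond the first and last point).  Runs separated by less
    than one slide step are merged.
    """
    above = series.values > threshold
    bouts: list[tuple[float, float]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            start = series.times[i] - series.slide / 2.0
            end = series.times[j] + series.slide / 2.0
            if bouts and start - bouts[-1][1] < series.slide:
                bouts[-1] = (bouts[-1][0], end)
            else:
                bouts.append((start, end))
            i = j + 1
        else:
            i += 1
    return [GroomingBout(start=s, end=e) for s, e in bouts]


def attribute_bout(
    bout: GroomingBout,
    trajectories: list,
    groom_location: np.ndarray,
    tick_rate: float = 7.4,
    gate: float = 500.0,
) -> GroomingBout:
    """Attach the <= 2 individuals nearest the grooming location.

    For each identified trajectory the median distance to the grooming
    location over the bout interval is computed (missing frames skipped);
    the two smallest medians within ``gate`` mm become the participants.
    An empty participant set keeps the bout but signals that every animal
    was missing or far away.
    """
    loc = np.asarray(groom_location, dtype=float)
    start_tick = int(np.floor(bout.start * tick_rate))
    end_tick = int(np.ceil(bout.end * tick_rate))
    medians = []
    for traj in trajectories:
        if traj.individual_id is None:
            continue
        ds = [
            float(np.linalg.norm(fr.position - loc))
            for fr in traj.frames
            if fr.position is not None and start_tick <= fr.tick <= end_tick
        ]
        if ds:
            medians.append((float(np.median(ds)), traj.individual_id))
    medians.sort()
    participants = tuple(pid for d, pid in medians[:2] if d <= gate)
    return GroomingBout(
        start=bout.start, end=bout.end, location=loc, participants=participants
    )


@dataclass(frozen=True)
class UnitEvaluation:
    recall_pct: float | None
    precision_pct: float | None
    units: "np.ndarray"  # structured per-unit table
    n_truth_positive: int
    n_machine_positive: int
    n_overlap: int


def _unit_positives(bouts: list[GroomingBout], edges: np.ndarray) -> np.ndarray:
    pos = np.zeros(len(edges) - 1, dtype=bool)
    for b in bouts:
        for k in range(len(pos)):
            if b.start < edges[k + 1] and b.end > edges[k]:
                pos[k] = True
    return pos


def evaluate_units(
    machine_bouts: list[GroomingBout],
    truth_bouts: list[GroomingBout],
    horizon: float,
    unit: float = 30.0,
) -> UnitEvaluation:
    """Score machine bouts against annotation in fixed 30-s units.

    The horizon is partitioned into ``unit``-second cells; a cell is
    positive for a source when any of that source's bouts overlaps it.
    Recall = overlapping / truth-positive units; precision = overlapping /
    machine-positive units (undefined -> None when a denominator is zero).
    """
    edges = np.arange(0.0, horizon + 1e-9, unit)
    if len(edges) < 2:
        raise ValueError("horizon shorter than one unit")
    m = _unit_positives(machine_bouts, edges)
    t = _unit_positives(truth_bouts, edges)
    overlap = int(np.sum(m & t))
    n_m, n_t = int(m.sum()), int(t.sum())

    def pct(num, den):
        return float(np.floor(1000.0 * num / den + 0.5) / 10) if den > 0 else None

    table = np.zeros(
        len(m), dtype=[("unit_start", float), ("machine", bool), ("truth", bool)]
    )
    table["unit_start"] = edges[:-1]
    table["machine"] = m
    table["truth"] = t
    return UnitEvaluation(
        recall_pct=pct(overlap, n_t),
        precision_pct=pct(overlap, n_m),
        units=table,
        n_truth_positive=n_t,
        n_machine_positive=n_m,
        n_overlap=overlap,
    )
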