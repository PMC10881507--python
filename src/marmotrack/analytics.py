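"""Trajectory analytics: zone occupancy, place preference, social distance.

Works on identified trajectories (per-tick 3D positions with missing
frames).  Occupancy classifies each valid tick into a named axis-aligned
cage zone (upper bed, middle floor, lower bed, lower floor) or the
catch-all "other"; missing ticks are excluded from the denominator.
Pairwise inter-individual distances are defined only on ticks where both
animals have a position — which is why different pairs have different
valid-frame denominators — and are summarised as fractions of time below
0.5 m, between 0.5 and 1 m, and above 1 m.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CageModel


@dataclass(frozen=True)
class Zone:
    """Named axis-aligned box in the cage frame (mm)."""

    name: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, p: np.ndarray) -> bool:
        return bool(np.all(np.asarray(p) >= self.lo) and np.all(np.asarray(p) <= self.hi))


def default_zones(cage: CageModel | None = None) -> list[Zone]:
    """Five-label layout on the standard family cage.

    Heights split the cage into a lower floor, a lower bed shelf, the
    middle floor, and the upper bed near the ceiling; everything else
    (including the transit band between middle floor and upper bed) is
    "other".  Zone boxes are configuration; this default is a plausible
    layout for the 820 x 610 x 1578 mm family cage.
    """
    cage = cage or CageModel()
    w, d, h = cage.width, cage.depth, cage.height
    return [
        Zone("upper_bed", (0, 0, 1150), (w, d, h)),
        Zone("middle_floor", (0, 0, 550), (w, d, 950)),
        Zone("lower_bed", (0, 0, 200), (w, d, 550)),
        Zone("lower_floor", (0, 0, 0), (w, d, 200)),
    ]


OTHER = "other"


def _validate_zones(zones: list[Zone]) -> None:
    names = [z.name for z in zones]
    if len(set(names)) != len(names):
        raise ValueError("duplicate zone names")
    for za, zb in combinations(zones, 2):
        lo = np.maximum(za.lo, zb.lo)
        hi = np.minimum(za.hi, zb.hi)
        if np.all(lo < hi):
            raise ValueError(f"zones {za.name!r} and {zb.name!r} overlap")


def classify_zone(position: np.ndarray, zones: list[Zone]) -> str:
    """First matching named zone, else "other"."""
    for z in zones:
        if z.contains(position):
            return z.name
    return OTHER


@dataclass(frozen=True)
class OccupancySummary:
    individual_id: str
    counts: dict[str, int]
    valid_frames: int

    def percent(self, zone: str) -> float:
        if self.valid_frames == 0:
            raise ValueError("no valid frames")
        return float(
            np.floor(1000.0 * self.counts.get(zone, 0) / self.valid_frames + 0.5) / 10
        )

    @property
    def percents(self) -> dict[str, float]:
        return {z: self.percent(z) for z in self.counts}


def zone_occupancy(traj, zones: list[Zone] | None = None) -> OccupancySummary:
    """Per-zone frame counts and percents for one identified trajectory."""
    zones = zones if zones is not None else default_zones()
    _validate_zones(zones)
    counts = {z.name: 0 for z in zones}
    counts[OTHER] = 0
    valid = 0
    for fr in traj.frames:
        if fr.position is None:
            continue
        counts[classify_zone(fr.position, zones)] += 1
        valid += 1
    return OccupancySummary(
        individual_id=getattr(traj, "individual_id", None) or "?",
        counts=counts,
        valid_frames=valid,
    )


def pairwise_distances(trajs: list) -> pd.DataFrame:
    """Per-tick Euclidean distance for every unordered pair of individuals.

    Returns a DataFrame (pair, tick, distance_mm); ticks where either
    animal is missing produce no row.
    """
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories")
    pos = {
        tr.individual_id: {
            fr.tick: fr.position for fr in tr.frames if fr.position is not None
        }
        for tr in trajs
        if tr.individual_id is not None
    }
    rows = []
    for ida, idb in combinations(sorted(pos), 2):
        shared = sorted(set(pos[ida]) & set(pos[idb]))
        for tick in shared:
            d = float(np.linalg.norm(pos[ida][tick] - pos[idb][tick]))
            rows.append((f"{ida}-{idb}", tick, d))
    return pd.DataFrame(rows, columns=["pair", "tick", "distance_mm"])


def distance_fractions(
    distances_mm: np.ndarray | pd.Series,
    thresholds: tuple[float, float] = (500.0, 1000.0),
) -> dict[str, float]:
    """Percent of valid ticks below / between / above the two thresholds."""
    d = np.asarray(distances_mm, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no valid distance records")
    low, high = thresholds
    if not 0 < low < high:
        raise ValueError("thresholds must be increasing and positive")

    def pct(n):
        return float(np.floor(1000.0 * n / d.size + 0.5) / 10)

    n_lt = int(np.sum(d < low))
    n_gt = int(np.sum(d > high))
    return {
        "lt_low_pct": pct(n_lt),
        "mid_pct": pct(d.size - n_lt - n_gt),
        "gt_high_pct": pct(n_gt),
        "n_valid": int(d.size),
        "n_lt_low": n_lt,
        "n_gt_high": n_gt,
    }


@dataclass(frozen=True)
class PreferenceGrid:
    """3D dwell-fraction histogram with a display saturation cap."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    fractions: np.ndarray
    saturated: np.ndarray  # cells above the display cap
    cap: float


def place_preference_grid(
    traj, cage: CageModel | None = None, cell: float = 100.0, cap: float = 0.01
) -> PreferenceGrid:
    """Per-cell dwell-time fractions over a regular 3D grid of the cage.

    Cells where the animal spent more than ``cap`` of its valid time are
    flagged saturated (the red cells of a place-preference heat map).
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    cage = cage or CageModel()
    pts = np.array(
        [fr.position for fr in traj.frames if fr.position is not None], dtype=float
    )
    edges = tuple(
        np.arange(0.0, dim + cell, cell)
        for dim in (cage.width, cage.depth, cage.height)
    )
    if pts.size == 0:
        shape = tuple(len(e) - 1 for e in edges)
        zero = np.zeros(shape)
        return PreferenceGrid(edges, zero, zero.astype(bool), cap)
    hist, _ = np.histogramdd(pts, bins=edges)
    frac = hist / pts.shape[0]
    return PreferenceGrid(edges, frac, frac > cap, cap)


def compare_to_observer(
    system: list[OccupancySummary] | dict[str, dict[str, float]],
    human: list[OccupancySummary] | dict[str, dict[str, float]],
) -> dict:
    """Pearson correlation between system and human zone-occupancy percents.

    Pairs are (individual, zone) percents present in both summaries.
    Returns r, r^2, n and the paired table.
    """

    def as_table(src):
        if isinstance(src, dict):
            return {
                (ind, z): p for ind, zones in src.items() for z, p in zones.items()
            }
        return {
            (s.individual_id, z): s.percent(z) for s in src for z in s.counts
        }

    sys_t, hum_t = as_table(system), as_table(human)
    keys = sorted(set(sys_t) & set(hum_t))
    if len(keys) < 3:
        raise ValueError("need at least three paired observations")
    x = np.array([hum_t[k] for k in keys])
    y = np.array([sys_t[k] for k in keys])
    r, p = stats.pearsonr(x, y)
    table = pd.DataFrame(
        {
            "individual": [k[0] for k in keys],
            "zone": [k[1] for k in keys],
            "human_pct": x,
            "system_pct": y,
        }
    )
    return {"r": float(r), "r_squared": float(r**2), "p_value": float(p), "n": len(keys), "table": table}
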