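"""Grooming smoothing, bout extraction, attribution, and unit evaluation."""

import numpy as np
import pytest

from marmotrack.behavior import (
    DetectionSeries,
    GroomingBout,
    SmoothParams,
    attribute_bout,
    combine_cameras,
    evaluate_units,
    extract_bouts,
    smooth_series,
)
from marmotrack.fusion import SOURCE_VIDEO, Frame
from marmotrack.identity import IdentifiedTrajectory

TICK = 0.135  # ~7.4 Hz


def series(values, tick=TICK, camera_id="cam"):
    values = np.asarray(values, dtype=float)
    return DetectionSeries(camera_id, np.arange(len(values)) * tick, values)


class TestSmoothing:
    def test_zero_input_zero_output(self):
        out = smooth_series(series(np.zeros(1000)), SmoothParams())
        assert np.all(out.values == 0)

    def test_constant_input_preserved(self):
        out = smooth_series(series(np.full(1000, 0.7)), SmoothParams())
        assert np.allclose(out.values, 0.7)

    def test_output_within_input_range(self, rng):
        vals = rng.uniform(0, 1, size=1500)
        out = smooth_series(series(vals), SmoothParams())
        assert np.all(out.values >= vals.min() - 1e-12)
        assert np.all(out.values <= vals.max() + 1e-12)

    def test_boxcar_pulse_edges_localized(self):
        """A 60-s rectangular pulse: the smoothed series crosses 0.5 within
        half a window of each true edge (closed-form: boxcar * Gaussian)."""
        horizon, t0, t1 = 300.0, 120.0, 180.0
        n = int(horizon / TICK)
        t = np.arange(n) * TICK
        vals = ((t >= t0) & (t < t1)).astype(float)
        p = SmoothParams(window=50.0, slide=5.0)
        out = smooth_series(series(vals), p)
        above = out.values > 0.5
        first = out.times[np.argmax(above)]
        last = out.times[len(above) - 1 - np.argmax(above[::-1])]
        assert abs(first - t0) <= p.window / 2
        assert abs(last - t1) <= p.window / 2


class TestCombineCameras:
    def test_identical_series_unchanged(self):
        s = smooth_series(series(np.ones(500)), SmoothParams())
        out = combine_cameras(s, s)
        assert np.allclose(out.values, s.values)

    def test_zero_and_one_average_to_half(self):
        a = smooth_series(series(np.zeros(500)), SmoothParams())
        b = smooth_series(series(np.ones(500)), SmoothParams())
        assert np.allclose(combine_cameras(a, b).values, 0.5)

    def test_equals_elementwise_mean_oracle(self, rng):
        a = smooth_series(series(rng.uniform(0, 1, 800)), SmoothParams())
        b = smooth_series(series(rng.uniform(0, 1, 800)), SmoothParams())
        out = combine_cameras(a, b)
        assert np.allclose(out.values, (a.values + b.values) / 2)

    def test_grid_mismatch_rejected(self):
        a = smooth_series(series(np.ones(500)), SmoothParams())
        b = smooth_series(series(np.ones(800)), SmoothParams())
        with pytest.raises(ValueError):
            combine_cameras(a, b)


class TestExtractBouts:
    def test_all_below_threshold_no_bouts(self):
        s = smooth_series(series(np.full(800, 0.2)), SmoothParams())
        assert extract_bouts(s, 0.5) == []

    def test_run_length_arithmetic(self):
        """Six consecutive supra-threshold slide points at 5-s slide span 30 s."""
        from marmotrack.behavior import ProbabilitySeries

        times = np.arange(0.0, 100.0, 5.0)
        vals = np.zeros_like(times)
        vals[4:10] = 0.9
        bouts = extract_bouts(ProbabilitySeries(times, vals, 5.0), 0.5)
        assert len(bouts) == 1
        assert bouts[0].end - bouts[0].start == pytest.approx(30.0)

    def test_bout_count_nonincreasing_in_threshold(self, rng):
        vals = np.clip(
            np.convolve(rng.uniform(0, 1, 2000), np.ones(50) / 50, mode="same"), 0, 1
        )
        s = smooth_series(series(vals), SmoothParams())
        counts = [len(extract_bouts(s, th)) for th in np.linspace(0.1, 0.9, 9)]
        diffs = np.diff(counts)
        assert np.all(np.array(counts) >= 0)
        # each higher-threshold bout is contained in some lower-threshold bout
        lo = extract_bouts(s, 0.3)
        hi = extract_bouts(s, 0.6)
        for b in hi:
            assert any(a.start <= b.start and b.end <= a.end for a in lo)

    def test_higher_threshold_bouts_nested(self, rng):
        vals = rng.uniform(0, 1, 1500)
        s = smooth_series(series(vals), SmoothParams())
        lo, hi = extract_bouts(s, 0.4), extract_bouts(s, 0.7)
        for b in hi:
            assert any(a.start <= b.start and b.end <= a.end for a in lo)


class TestAttributeBout:
    def _traj(self, pid, pos, n=200):
        return IdentifiedTrajectory(
            pid,
            [Frame(k, np.asarray(pos, dtype=float), SOURCE_VIDEO) for k in range(n)],
        )

    def test_two_near_animals_attributed(self):
        loc = np.array([300.0, 300.0, 1200.0])
        trajs = [
            self._traj("A", loc + [50, 0, 0]),
            self._traj("B", loc - [50, 0, 0]),
            self._traj("C", [700, 100, 100]),
        ]
        bout = attribute_bout(GroomingBout(5.0, 15.0), trajs, loc, tick_rate=7.4)
        assert set(bout.participants) == {"A", "B"}

    def test_all_missing_gives_empty_participants(self):
        trajs = [
            IdentifiedTrajectory("A", [Frame(k, None, "missing") for k in range(200)])
        ]
        bout = attribute_bout(
            GroomingBout(5.0, 15.0), trajs, np.array([300.0, 300.0, 1200.0])
        )
        assert bout.participants == ()

    def test_far_animals_outside_gate_excluded(self):
        loc = np.array([300.0, 300.0, 1200.0])
        trajs = [self._traj("A", [700, 100, 100])]
        bout = attribute_bout(GroomingBout(5.0, 15.0), trajs, loc, gate=400.0)
        assert bout.participants == ()


def units_oracle(machine, truth, horizon, unit):
    """Brute-force per-unit positivity table."""
    n = int(np.floor(horizon / unit + 1e-9))
    m = [any(b.start < (k + 1) * unit and b.end > k * unit for b in machine) for k in range(n)]
    t = [any(b.start < (k + 1) * unit and b.end > k * unit for b in truth) for k in range(n)]
    return m, t


class TestEvaluateUnits:
    def test_published_unit_counts_give_published_metrics(self):
        """24 truth-positive units, 21 machine-positive, 19 overlapping
        -> precision 90.5%, recall 79.2%."""
        unit = 30.0
        truth, machine = [], []
        # 19 shared units, 5 truth-only, 2 machine-only, inside a 1-h horizon
        for k in range(19):
            truth.append(GroomingBout(k * 60.0 + 5, k * 60.0 + 25))
            machine.append(GroomingBout(k * 60.0 + 5, k * 60.0 + 25))
        for j in range(5):
            truth.append(GroomingBout(1500.0 + j * 60.0 + 35, 1500.0 + j * 60.0 + 55))
        for j in range(2):
            machine.append(GroomingBout(2010.0 + j * 60.0, 2030.0 + j * 60.0))
        ev = evaluate_units(machine, truth, horizon=3600.0, unit=unit)
        assert ev.n_truth_positive == 24
        assert ev.n_machine_positive == 21
        assert ev.n_overlap == 19
        assert ev.precision_pct == 90.5
        assert ev.recall_pct == 79.2

    def test_machine_equals_truth_perfect(self):
        bouts = [GroomingBout(10.0, 50.0), GroomingBout(200.0, 260.0)]
        ev = evaluate_units(bouts, bouts, horizon=600.0)
        assert ev.recall_pct == 100.0 and ev.precision_pct == 100.0

    def test_no_machine_positives_precision_undefined(self):
        ev = evaluate_units([], [GroomingBout(10.0, 50.0)], horizon=600.0)
        assert ev.precision_pct is None
        assert ev.recall_pct == 0.0

    def test_matches_brute_force_oracle_on_random_bouts(self, rng):
        for _ in range(10):
            horizon = 900.0
            mk = lambda: [
                GroomingBout(float(s), float(s) + float(rng.uniform(5, 120)))
                for s in rng.uniform(0, horizon - 130, size=rng.integers(1, 8))
            ]
            machine, truth = mk(), mk()
            ev = evaluate_units(machine, truth, horizon=horizon)
            m, t = units_oracle(machine, truth, horizon, 30.0)
            assert list(ev.units["machine"]) == m
            assert list(ev.units["truth"]) == t

    def test_swap_symmetry_exchanges_recall_precision(self, rng):
        mk = lambda: [
            GroomingBout(float(s), float(s) + 40.0)
            for s in rng.uniform(0, 500, size=5)
        ]
        a, b = mk(), mk()
        ev_ab = evaluate_units(a, b, horizon=600.0)
        ev_ba = evaluate_units(b, a, horizon=600.0)
        assert ev_ab.recall_pct == ev_ba.precision_pct
        assert ev_ab.precision_pct == ev_ba.recall_pct
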