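# marmotrack

Multi-animal 3D tracking and behavior analytics for home-cage monitoring of
small primates (common marmosets), combining multi-view camera
triangulation with lidar point-cloud cluster tracking, face-recognition
based identity assignment, and downstream social-behavior analytics.

## The problem

Marmoset families live in a tall cage (820 × 610 × 1578 mm) and move fast in
three dimensions. Long-term, marker-less observation of *each individual*
requires three things no single sensor provides:

1. **Position.** Four calibrated front cameras detect each animal's body per
   frame; bounding-box centres from ≥ 2 views are triangulated by direct
   linear transform into cage-frame 3D points. Video is precise but loses
   animals during fast jumps and occlusion. A lidar stream — background
   subtracted by voxel occupancy, segmented by Euclidean cluster extraction
   with size gates S1 = 100 mm and S2 = 500 mm, cluster centroids tracked
   with serial IDs — misses little motion but is fooled by marmoset-sized
   clutter (tails, feeders, balls). The fusion tracker uses video as the
   primary source and hands off to lidar within a gate when video drops out,
   producing anonymous tracklets with per-tick source labels
   (`video`/`lidar`/`missing`); out-of-cage coordinates become missing
   values.
2. **Identity.** A face classifier intermittently emits (time, position,
   predicted individual, confidence) events. Each event attaches to the
   nearest tracklet; per-frame identities come from a recency-weighted
   confidence vote with per-tick one-to-one assignment of individuals to
   tracklets, so identity is re-established as soon as a face is seen after
   a huddle or crossing.
3. **Behavior.** Per-frame grooming detections from the two upper cameras
   are smoothed with a Gaussian-weighted moving average (50-s window, 5-s
   slide), averaged across cameras, and thresholded into grooming bouts,
   each attributed to the ≤ 2 individuals nearest the grooming location.
   Analytics then quantify zone occupancy, place preference and
   inter-individual distance bands (< 0.5 m / 0.5–1 m / > 1 m).

Because no public recordings exist for such a rig, the package includes a
first-class simulator that generates ground-truth scenes (waypoint motion,
scripted huddles, grooming bouts at fixed spots, excursions into a connected
cage) and renders every sensor stream with configurable noise, miss, and
clutter models — so the whole pipeline is testable end to end.

## Worked example

```python
from marmotrack import simulator
from marmotrack.pipeline import run_on_scene
from marmotrack.identity import correct_id_fraction

scene = simulator.preset_scene("family3", horizon=300.0, seed=42)
res = run_on_scene(scene)
truth = simulator.truth_tick_maps(scene.trajectories)
print(res.stats)
print(correct_id_fraction(res.trajectories, truth))
```

On a 5-minute simulated three-animal family scene this prints (values from
an actual run):

```
tracklets: 27  mean duration: 40.4 s
source fractions: video 0.81  lidar 0.14  missing 0.06
correct-ID tick fraction: 0.965
A: 2215 frames, mostly lower_bed (62.3%)
C: 2084 frames, mostly upper_bed (48.6%)
B: 2201 frames, mostly upper_bed (41.3%)
B-C: <0.5 m 57.4%  >1 m 9.1%  (n=2066)
grooming bouts: [(62, 98, ('B', 'C')), (212, 248, ('C', 'B'))]
```

Reading: the tracker produced 27 anonymous tracklets averaging 40 s; 81% of
fused positions came from video with lidar bridging 14%; 96.5% of
(animal, tick) ground-truth samples carried the right identity. The
scripted grooming pair (B grooms C at an upper cage location from t = 62 s)
was recovered with the correct participants. Distance fractions use only
ticks where both animals have positions, so each pair has its own
denominator.

The same stages are available from a CLI:

```bash
marmotrack simulate family3 --out scene/ --horizon 120 --seed 7
marmotrack track scene/ --out results/
marmotrack analyze results/trajectories.csv
marmotrack evaluate results/trajectories.csv --truth scene/truth.csv
```

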