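# Methods

This note documents the models, parameters and numerical choices behind
marmotrack, and what the simulator-based tests do and do not demonstrate.

## Coordinate frame and geometry

The cage frame has its origin at the front-lower-left corner: x along the
width (0–820 mm), y along the depth (front face at y = 0, cameras at
negative y), z height (0–1578 mm); all lengths in millimetres. Cameras are
undistorted pinhole models. Pose calibration uses the four front-face
corner fiducials: because they are coplanar, the pose follows from a planar
homography decomposition (intrinsics are configuration, not estimated) and
is refined by Levenberg–Marquardt on marker reprojection error. With 1 px
marker noise the recovered pose localises an interior point at ~1 m range
to well under 20 mm (Monte-Carlo bound in the test suite).

Triangulation is linear least squares on the stacked ray equations (solved
through the 3×3 normal equations). With three or more views, one view whose
reprojection residual exceeds 3× the median of the others is dropped and
the solve repeated — enough to reject a single cross-associated or false
detection. Rays with < 1° maximal pairwise parallax (e.g. a target on the
two-camera baseline) are flagged low-confidence rather than silently
returned. The default four-camera rig places two columns 600 mm apart,
1000 mm in front of the cage, at 900 and 1900 mm height, aimed at the cage
centre; the default focal length (620 px at 1920×1080) is the longest that
keeps the full cage in every view. At 1 px detection noise this rig gives
a median 3D error below 15 mm.

## Lidar pipeline

Background is a voxel-occupancy set (default 30 mm voxels) built from
animal-free scans; foreground points are those in free voxels. Clustering
is Euclidean cluster extraction: connected components of the
fixed-radius neighbour graph (KD-tree + union of components), with a
50 mm linking tolerance. The size gates S1 = 100 mm and S2 = 500 mm are
interpreted as spatial extent (maximum axis-aligned span), since they are
lengths at marmoset body scale; components outside [S1, S2] are discarded.
Cluster centroids (arithmetic means) feed a serial-ID tracker: per scan, a
global minimum-cost (Hungarian) assignment links centroids to live tracks
within a 300 mm gate; unmatched centroids open new serials; a track silent
for more than 1 s closes. Serial numbers are never reused — a broken
trajectory always gets a fresh number.

## Cross-view association and fusion

Per analysis tick (default 7.4 Hz), body detections are grouped across
cameras by hypothesising every cross-camera pair, extending each hypothesis
with the best-reprojecting detection from the remaining cameras, and
accepting disjoint hypotheses in order of triangulation residual (gate
15 px). Hypotheses triangulating outside the cage volume are rejected:
rays from two *different* animals can intersect almost exactly, but the
ghost intersection almost always lies far outside the cage box. An
exhaustive joint-assignment mode (≤ 4 animals) serves as the oracle in
tests.

Fusion extends each live tracklet per tick with (1) the nearest unclaimed
video point within the motion gate (300 mm per tick, scaled by elapsed
ticks), else (2) the nearest unclaimed lidar centroid within the 200 mm
handoff gate of the last known position, else (3) a missing frame; after
1 s of missing the tracklet closes. Only unclaimed *video* points seed new
tracklets, so lidar clutter cannot create ghost tracks. The handoff gate
is deliberately smaller than the tracker's motion gate: simulated tail
false clusters sit ~350 mm off-body, and a 200 mm gate keeps them out of
reach while still bridging occlusions; likewise the 1-s break threshold
trades tracklet length for identity safety — a broken tracklet is
re-identified by the next face observation, whereas a long gap bridged to
the wrong animal poisons every subsequent frame. Both values are
configuration. No smoothing or filtering is applied; fused output is the
raw switched coordinates.

## Identity

Face-classification events (time, 3D position, predicted individual,
confidence; an `unknown` class filters unusable crops and is discarded)
attach to the nearest tracklet position within 200 mm, tolerating one tick
of clock skew. Identities are voted per frame with recency weighting:
observation weight = confidence × exp(−|Δt|/τ), τ = window/8 = 7.5 s for
the default 60-s window, so a tracklet that swapped animals mid-stream is
relabelled within a few observations of the swap instead of carrying one
label to its end. Per tick, identities are assigned to tracklet frames by
a maximum-vote-mass one-to-one (Hungarian) assignment — when two tracklets
both look like individual B, the weaker claim falls back to its
second-best identity rather than going unlabelled. Exact vote ties stay
unidentified.

Classifier quality metrics are standard one-vs-rest specificity, accuracy,
recall, precision and F-measure, reported as percentages rounded half-up
to one decimal; zero-denominator metrics are reported as undefined rather
than coerced. F computed from a table's own printed precision/recall can
differ by 0.1 from a published F computed before rounding; the
implementation always computes from its inputs. The ID-switch report
scores labelled trajectories against per-tick truth: a frame is wrong when
its position is nearer another individual's true position; maximal wrong
runs ≥ 5 s count as switches, and the wrong-ID fraction is their summed
duration over the record horizon.

## Grooming detection

Per-camera 0/1 grooming indicators are smoothed by a Gaussian-weighted
moving average over a 50-s window evaluated every 5 s. The Gaussian width
is not independently specified, so σ = window/6 (≈ 99.7% of mass inside
the window); weights are renormalised in truncated edge windows, making
the smoother exactly constant-preserving. The two cameras' series are
averaged pointwise and thresholded (default 0.5 on the averaged frequency
scale; configuration) into maximal supra-threshold runs; a run of k slide
points spans k × 5 s. Bouts are attributed to the ≤ 2 individuals with the
smallest median distance to the grooming location during the bout (500 mm
proximity gate); the grooming location is the midpoint of the nearest pair
of animals over the bout interval. Evaluation partitions the timeline into
30-s units; a unit is positive for a source when any bout overlaps it, and
recall/precision are computed on unit counts.

## Analytics

Zone occupancy classifies each valid tick by point-in-box against named
zones with an "other" complement; missing ticks leave the denominator. The
default five-zone layout (upper bed z > 1150, middle floor 550–950, lower
bed 200–550, lower floor < 200, full cage cross-section each) is a
plausible assignment for the standard family cage — real installations
should supply measured boxes via configuration. Pairwise distances exist
only where both animals have positions, so pair denominators differ by
construction. Distance bands use 0.5 m / 1 m thresholds; place-preference
grids report per-cell dwell fractions with a 1% saturation cap; the
human-vs-system comparison is a plain Pearson correlation over paired
(individual, zone) percentages.

## Simulator

The simulator defines the test conditions. Motion is a waypoint state
machine per agent — rest, locomote (100–500 mm/s), jump (up to 3000 mm/s;
documented guesses at marmoset scale) — with scripted events overriding
free motion: huddles and grooming bouts pull participants within 100 mm of
a fixed location; excursions mark the agent off-volume. Sensors are
rendered from truth: camera detections with 1 px pixel noise, a
speed-dependent miss model (5% base, up to +50% at jump speed), scripted
occlusion windows and Poisson false positives; lidar as Gaussian body
blobs (~60/40/40 mm axes, 80 points) plus tail-like ~120 mm false clusters
offset 350 mm from the body; face events at 0.2 /s when the face is
visible (suppressed while huddled or occluded) from a confusion-matrix
surrogate classifier (default accuracy 0.98, 10% `unknown` rate); grooming
indicators with 0.8 per-frame hit rate during scripted bouts and 2% false
alarms. All randomness derives from one seed; identical configuration and
seed reproduce bit-identical scenes and fixtures.

What passing simulations show — correct geometry, association, fusion
logic, identity voting and analytics under controlled noise — and what
they do not: real detector behaviour (correlated misses, bbox drift,
merged boxes in huddles), real lidar phenomenology (rings, reflections,
partial returns), appearance-dependent face-classifier errors, and real
marmoset kinematics. The headline identity numbers here are therefore
statements about the linking algorithm under the stated surrogate models,
not about any particular hardware installation.

## Problem sizes

Tests and the acceptance script run family scenes of 60–300 s at 7.4 Hz
with three animals (the identity criterion pools 20 seeds × 120 s), sizes
chosen so the full suite and script each complete in minutes on one CPU
while every stage still sees hundreds of ticks per scene. Arithmetic-only
metrics (occupancy, distance bands, unit evaluation, classifier tables)
use the full published frame counts, which cost nothing to evaluate.

## Known limitations

- Association is greedy over pair hypotheses; pathological geometries with
  many in-cage ghost intersections could still confuse it (the exhaustive
  oracle exists only for ≤ 4 animals).
- Identity assignment assumes face positions and tracklets share a clock
  to within one tick.
- The smoother's output grid starts at the first sample, so bout times are
  quantised to the 5-s slide.
- Zone layouts and the grooming threshold are defaults, not measurements;
  analyses that depend on them must configure real values.
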