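# Methods

`tdcai` turns a registered 4D CT-perfusion (CTP) series into angiographic
derivatives: skull-stripped vessel volumes, separated arterial/venous
(CTA/CTV) images, a centerline for a chosen vessel-of-interest, and a
straightened (curved-planar-reformatted) rendering of that vessel.  This
note documents the model behind each stage, the tunable parameters, the
synthetic phantoms used for validation, and the numerical choices made
where the design was genuinely open.

## Pipeline model

**Skull stripping.**  Bone attenuates far more than soft tissue, so the
skull mask is simply `first frame >= 155 HU` (the first frame is the
pre-contrast registration benchmark).  Everything outside the largest
cavity enclosed by that mask is treated as extracranial and blanked to an
air sentinel of −1024 HU; when the image contains no enclosing shell, all
non-bone voxels are kept, so the operation degrades to the identity on
shell-less inputs.  The mask is 3D and applied uniformly over time, which
preserves the brain voxel count across frames and makes the operation
idempotent.  Rigid registration itself is out of scope: inputs are assumed
registered (the phantoms are born registered).

**Vessel segmentation.**  Each voxel's time-attenuation curve (TAC) is
correlated with a digitized first-order derivative-of-Gaussian kernel
(default 1×5 taps, σ = 3 in frame-index units; taps are odd-antisymmetric
with an exactly zero sum, so constants are annihilated and the response is
positive on contrast uptake).  The per-voxel feature is

    FG = Σ_i |v′_i| ,

the summed absolute filter response over frames.  FG is zero on constant
curves, invariant to DC offsets, and linear in TAC amplitude, so vessels
(large, fast enhancement) separate from parenchyma by a single threshold.
The default threshold is Otsu's method on the log(FG+1) histogram
restricted to FG > 0 voxels; restricting removes the exactly-zero
background mass that would otherwise dominate the histogram.  Series
boundaries use edge replication, which keeps the derivative zero on flat
baselines at both ends.

**Artery/vein separation.**  The time-to-peak (TTP) of the smoothed TAC is
the zero crossing of v′: at the first frame t_{I+1} where v′ turns
non-positive after the uptake, a line through (t_I, v′_I) and
(t_{I+1}, v′_{I+1}) is intersected with zero,

    a = (v′_{I+1} − v′_I)/(t_{I+1} − t_I),  b = v′_{I+1} − a·t_{I+1},
    t_ttp = −b/a .

Two numerical choices: a flat crossing (a = 0) returns t_{I+1}, the
zero-slope limit of the interpolation; and the crossing search is anchored
*after the global maximum of v′*.  On clean curves the anchored rule is
identical to "first negative v′", but on noisy late-arriving (venous)
curves the literal rule fires on sub-noise baseline wiggles — at 5 HU
noise roughly half of the venous voxels in the CTP phantom would otherwise
receive pre-bolus TTPs.  Voxels whose derivative never turns negative
(curves truncated by scan end) get TTP = NaN and are assigned to the vein
mask, the latest possible arrival.

Contrast reaches arteries earlier than veins, so the TTP histogram over
vessel voxels is bimodal.  The threshold V_ttp is the center of the
lowest-count bin strictly between the two highest-prominence peaks
(ties break toward the lower TTP, a deterministic rule that favors venous
sensitivity).  Bins default to 4× the number of frame intervals over the
observed TTP range; a peak must have prominence of at least 10% of the
histogram maximum, so noise bumps on a unimodal histogram raise an error
advising a manual threshold instead of producing an arbitrary split.
Arteries are vessel voxels with TTP ≤ V_ttp, veins the rest.

**Centerline extraction.**  For a vessel-of-interest mask (an input; VOI
segmentation is a manual step outside this package):

1. the wall is the mask minus its erosion;
2. a closed triangle surface is built by marching cubes on the filled
   wall at the 0.5 isolevel, followed by five Laplacian smoothing
   iterations (the raw isosurface of a binary mask overestimates areas by
   ~10% through voxel staircase);
3. section planes are marched from the start seed toward the end seed;
   every closed plane–mesh intersection contour contributes one node with
   its area-weighted centroid and enclosed area;
4. Dijkstra's algorithm over the centroid graph returns the path between
   the snapped seeds, and that ordered point sequence is the centerline.
   Tangents are forward/central/backward differences, normalized.

The machinery around steps 3–4 is where the published sketch is silent and
the design was open; the choices below were driven by the branched-tube
phantom experiment (side branches are precisely the failure mode the
experiment probes):

* *March steering.*  The plane normal starts as the seed-pair direction
  and is re-estimated from consecutive accepted main centroids, but the
  turn rate is capped at 3°/step (cerebral-scale vessels at 1 mm steps
  curve well under that; uncapped updates let the march lock onto a 45°
  side branch).  A slice's main centroid is accepted for steering only if
  it lies within 1.5 steps of the predicted position *and* its contour
  area is within 1.4× the running median — merged junction contours fail
  the area check and the march extrapolates straight through them.
* *Graph edges.*  Centroids of sections up to 12 slices apart are joined
  (Euclidean weights).  At a branch junction the main contour merges with
  the branch opening for several consecutive slices (runs up to ~8 at
  1 mm steps were observed) and their centroids are displaced; a window of
  forward edges lets the shortest path hop over the whole run, which
  adjacent-only edges cannot.
* *Path cost.*  Pure metric shortest paths corner-cut in curved vessels: a
  centroid displaced toward the inside of the curve *shortens* the route
  and gets selected.  The path cost therefore adds (i) a squared
  turning-angle penalty of 4 mm/rad² — of the order of half a typical hop
  length, enough that a kink costs more than the fraction of a millimetre
  it saves — and (ii) a contour-area-excess penalty: nodes whose area
  exceeds the per-slice-maximum median by more than the excess threshold
  pay proportionally.  A merged junction contour is the union of two
  lumens, so the area jump is the sharp geometric signature of centroid
  displacement; a *sustained* caliber change (a real dilation) shifts all
  candidate nodes in its slices equally and cannot redirect the path.
* *Two-pass refinement.*  The adaptive march accumulates oblique-cut
  distortion in curved vessels (a tilted plane cuts an ellipse, inflating
  both centroid error and area).  A second pass re-slices the mesh with
  normals taken from the first-pass path tangents; sections are then
  orthogonal, clean contour areas sit within ~2% of the lumen median, and
  the junction detector can be sharpened to 5% excess (at 20 mm per unit
  excess).  The guide is extrapolated 5 mm past both path ends so the end
  seed snaps to a clean section even when the adaptive march stalls inside
  a junction near a seed; planes beyond the lumen intersect nothing and
  drop out.
* Seeds snap to the nearest centroid within 5 mm; farther seeds are an
  error.  Optional Laplacian path smoothing (3-point average, 2 passes)
  exists but is off by default, and all validation metrics are computed on
  the unsmoothed path.

The package also exposes the largest-inscribed-sphere radius along the
path (distance to the nearest wall voxel) as a quality metric, matching
the textbook definition of a centerline; it is a diagnostic, not part of
the extraction.

**Straightening.**  A square sampling grid of (2m+1)² points, initially
perpendicular to the z-axis, is carried along the centerline.  Between
consecutive points the tangent rotates by θ = arccos(n̂_{i−1}·n̂_i) about
û = n̂_{i−1}×n̂_i/‖·‖, and every grid offset is rotated by the Rodrigues
formula

    v′ = cos θ·v + (1−cos θ)(û·v)û + sin θ(û×v)

then re-attached at the next point.  Sequential minimal rotations are the
discrete rotation-minimizing frame, so the tube acquires no spurious
twist.  Parallel tangents (zero cross product) step by pure translation;
anti-parallel tangents are rejected as a non-physical fold-back.  The
rotation axis is oriented so that rotating n̂_{i−1} yields n̂_i under the
right-hand convention (the opposite cross-product order with an unsigned
angle rotates the wrong way).  The centerline is resampled to uniform
arc-length steps (default 0.5 mm) before propagation because
central-difference tangents behave poorly on the uneven node spacing a
shortest path produces.  Image values are trilinearly interpolated at
every grid point (4D series frame-by-frame, no temporal interpolation; a
flag selects all frames, a temporal MIP, or one frame), out-of-grid
samples receive a sentinel, and the planes are stacked along a new z-axis.
Plane half-size defaults to 10 mm and in-plane spacing to the source
in-plane voxel size.

**Caliber assessment.**  On a straightened binary or high-contrast tube,
the lumen area per slice is the count of above-threshold samples times the
in-plane spacing squared.  Slices below 0.75× the median area are flagged
narrow and above 1.25× dilated (configurable); contiguous runs merge into
arc-length intervals, and the minimum/maximum-area slice indices localize
the extremal caliber.

## Synthetic phantoms

All validation runs on programmatically generated phantoms with analytic
ground truth; no external data is used anywhere.

*Dynamic CTP scenes* place tubular "arteries" and "veins" (defaults:
straight tubes of radius 2 and 2.5 mm), an optional soft-tissue ellipsoid
and an ellipsoidal 1000 HU skull shell on a 64³ grid at 0.5 mm isotropic
spacing, 20 frames 2 s apart.  Every labelled voxel carries its class's
gamma-variate bolus curve

    enhancement(t) = A·((t−t0)/(αβ))^α · e^{α−(t−t0)/β}   (t > t0)

on a flat 40 HU baseline — the standard perfusion bolus model, chosen
because its peak time t0 + αβ is closed-form and serves as ground-truth
TTP.  Defaults: artery t0 4 s, α 3, β 2 (peak 10 s, 300 HU); vein t0 12 s,
α 4, β 2 (peak 20 s, 250 HU); soft tissue peaks at 18 s with 25 HU.
Optional additive Gaussian HU noise is the only randomness; with σ = 0
every voxel's TAC equals its label's model exactly, which the tests
exploit for exact oracles.

*Deviation phantoms* are curved tubes (circular arcs, radius of curvature
35–50 mm, length 45 mm, main radius 3 mm) with 0, 3, or 6 straight side
branches at 45–90° take-off, radius 40–60% of the main tube, length
8–12 mm, rasterized at 0.5 mm.  The analytic arc is the reference
centerline; deviations are exact point-to-polyline distances from the
extracted path nodes to that axis.

*Stenosis phantoms* are gently curved tubes (curvature radius 80–120 mm,
length 60 mm, radius 3 mm) with one stenosis (radius factor 0.5) and one
dilation (factor 1.5), each 10 mm long at randomized non-overlapping
arc-length intervals.  A phantom counts as correctly represented when the
straightened image's minimum-area slice falls in the stenosis interval and
its maximum-area slice in the dilation interval, judged with a half-slice
(±0.25 mm) allowance because a 0.5 mm slice represents that much arc
length.

What the phantoms do *not* emulate: partial-volume blur at vessel edges,
beam hardening, motion, patient anatomy, or realistic vascular trees.
Passing tests therefore demonstrate the geometric and temporal machinery
is correct under known ground truth, not clinical-grade performance on
patient data.

## Problem sizes and determinism

The validation experiments use 10 phantoms per branch count (30 total) and
20 stenosis phantoms — desk-scale suites that run in about a minute each
on one CPU.  All pipeline stages are deterministic: randomness exists only
in phantom generation, seeded explicitly, so identical configurations
reproduce byte-identical outputs, and the manifests record every
auto-chosen threshold (FG threshold, V_ttp) for replay with explicit
values.

## Known limitations

* The published description mentions digitizing the Gaussian derivative as
  "two filters" but only ever uses the first-order response; this package
  implements the single first-order filter.
* Only a single path is extracted between two seeds — no bifurcation-tree
  centerlines.
* Rigid registration is not implemented; misregistered input series will
  corrupt every TAC-based stage.
* The artery/vein split is a global TTP threshold: arterialized venous
  structures or delayed arterial filling (pathology) can be mislabelled.
* Straightening assumes the centerline is accurate; centerline error
  translates directly into lumen-area error in the straightened image.
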