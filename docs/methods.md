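# Methods

`rowtrack` is a tracking-by-detection pipeline for row crops observed by a
nadir camera on a moving field platform (a spray robot driving along
lettuce lanes is the motivating case).  The detector is external: the
package consumes per-frame axis-aligned bounding boxes and assigns each box
a persistent plant identity, including across long out-of-view gaps caused
by the platform stopping or reversing.  This note records the model, its
assumptions, the tunable parameters, the design choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## The model

**Assumption: plants are immobile on the ground.**  All apparent motion in
the image is camera-induced translation along the lane direction.  This is
what makes two things possible that general-purpose multi-object trackers
cannot do for visually identical targets: a *geometric* identity feature,
and exact re-identification after arbitrarily long absences.

**Row geometry.**  The lane structure appears in the image as near-vertical
columns of boxes.  A center line `x = k·y + b` is fitted to the box centers
by least squares of x on y (exact on collinear input, well-conditioned for
vertical columns).  For two lanes, two detections share a lane iff the
product of their signed residuals `r = k·cy + b − cx` is positive; for more
lanes the residuals are clustered with a deterministic 1-D k-means
(quantile initialization + Lloyd iterations — no randomness, so the whole
pipeline stays deterministic).  Within a lane, detections are ordered by
`cy` (ties by `cx`).  The first and last detections of each lane are *edge
plants*; everything between is a *middle plant*.

**Identity feature.**  A middle plant with center `(x, y)`, upper neighbor
`(x₁, y₁, w₁, h₁)` and lower neighbor `(x₂, y₂, w₂, h₂)` gets

    F = [ c₁·√((x₁−x)² + (y₁−y)²),
          c₂·√((x₂−x)² + (y₂−y)²),
          c_w·w₁/w₂,
          c_h·h₁/h₂ ]

compared by the Euclidean distance `‖F¹ − F²‖`.  Because ground positions
are fixed, F is invariant to camera translation; the planting jitter of a
real field makes it (weakly) discriminative between plants.

*Weights.*  The distance components are pixel-scale while the ratios are
order one.  By default `c₁ = c₂ = 1/S` with `S` the median in-lane neighbor
spacing of the current frame, and `c_w = c_h = 1`; this puts all four
components on the same order-one scale, so the fused cost below (which
subtracts an IOU in [0, 1]) is well balanced.  All four weights are
user-configurable.

**Motion model.**  Each tracked plant carries a constant-velocity Kalman
filter with state `(cx, cy, w, h, vcx, vcy)` — no size velocities, since
box sizes are quasi-constant between frames for ground-fixed plants.
Defaults (all configurable, chosen for 30 Hz imagery where the inter-frame
shift is a few pixels): measurement σ = 1 px per observed component,
process σ = 1 px on position/size and 10 px/frame on velocity, new tracks
start with zero velocity and an inflated velocity σ of 10 px/frame.  The
correction step uses the Joseph form so the covariance stays symmetric
positive semidefinite.

**Fused association.**  Middle detections are matched per lane against a
window of object-library candidates through

    Matrix_final = Matrix_feat − Matrix_IOU

(feature distance minus the IOU between the detection and the candidate's
Kalman-predicted box), solved by the Hungarian algorithm; assigned pairs
costing more than `tau_final` are demoted to unmatched.  A candidate
without a stored feature takes the neutral cost `tau_feat`; a candidate
that is out of view contributes zero IOU, so the cost degrades gracefully
to feature-only matching — which is exactly the re-identification
mechanism.

**Object library and candidate window.**  The library stores every plant
ever seen: ID, lane, in-lane planting ordinal, last box, Kalman state, and
identity feature; it never forgets.  Candidates for a frame are the
entries within `[a − x₁, a + x₂]` of the anchor `a` — the largest-ordinal
same-lane entry seen most recently.  The window is indexed in *ordinal*
space rather than raw ID numbers: with two or more lanes, IDs interleave
across lanes and raw-ID arithmetic breaks, while per-lane planting order
preserves the window's intent (spatial adjacency).  A raw-ID mode remains
available for single-lane data.  The radii must cover the number of plants
simultaneously visible; the defaults (`x₁ = x₂ = 3`) suit the reference
geometry of three to four plants per column, and the benchmark scenarios
size them from `(image height + box height)/spacing + 2`.

**Travel direction and edge plants.**  The drift direction is the median
of `Δcy` over plants tracked in consecutive frames (median for robustness
to individual mismatches; dead band `eps_dir = 2 px`).  Edge plants have
no feature, so they are resolved directionally: the *leaving* side is
matched to Kalman predictions by maximum IOU; on the *entering* side, an
edge detection first tries IOU continuity against existing predictions
(it may have been minted a few frames ago and is simply growing into the
view), and otherwise its planting ordinal is inferred from its pixel
distance to the nearest tracked middle plant.  If that ordinal lies beyond
the lane's known extent the plant is genuinely new and a fresh ID is
minted; if the library already has an entry there, the plant is
re-identified — this is how a reversing run restores the IDs of plants
that left the view.  Gap counts are measured on the box side *away* from
the image border, because an entering box is clipped and its center
shifted, while its inner edge is exact.

## Robustness under detector noise

The association above is exact when every plant is detected every frame.
Real detectors miss plants and jitter boxes, and several failure modes
only appear then.  The pipeline handles them explicitly; all of these
leave noise-free behavior unchanged:

1. **Suspect features are not extracted.**  If a middle detection's
   neighbor gap exceeds 1.5× the in-lane spacing, the true neighbor was
   not detected this frame and the feature would describe the wrong plant
   pair.  The detection competes on IOU alone that frame.
2. **Border-clipped features are not stored.**  A feature computed while
   any of the three boxes touches the image border is usable for matching
   within the frame but never written to the library: the clipped center
   is shifted, and the stored feature must describe the plant, not the
   viewport.
3. **Admissibility gating.**  A detection–candidate pair enters the
   Hungarian problem only if it overlaps the candidate's prediction
   (in-view continuity) or is a position-consistent re-identification: an
   out-of-view candidate within the feature gate whose ordinal is within
   ±1 of the detection's own ordinal as read off the in-view predictions.
   Without this, a chance feature coincidence deep in the library can
   steal a detection from its motion-confirmed track — plants are nearly
   identical, so feature coincidences are common.
4. **Reserved slots for missed plants.**  Cold-start ordinals increment by
   the rounded gap count, so a plant the detector misses in the very first
   frame keeps an empty slot in the planting order; when it appears later
   it is minted into that slot.  If the numbering has no room (the hole
   was created in a way the enumeration could not see), the lane is
   renumbered.  Detections that still cannot be placed — typically false
   positives sitting between two adjacent tracked plants — are deferred
   and omitted from that frame's output.

## Evaluation metrics

`rowtrack.metrics` scores tracker output against ground truth with the
identity family and HOTA.

*Identity measures.*  A one-to-one trajectory matching between ground-truth
and predicted IDs maximizes IDTP — the number of frames where a gt box and
its matched prediction ID are co-located (IOU ≥ 0.5) — via the Hungarian
algorithm on the co-location count matrix.  Then
`IDF1 = 2·IDTP/(2·IDTP + IDFP + IDFN)`, `IDR = IDTP/(IDTP+IDFN)`,
`IDP = IDTP/(IDTP+IDFP)`.  These are invariant to consistent relabeling of
predicted IDs, which is the correct notion for spray applications: any
stable labeling prevents double spraying.  IDSW counts frames where a gt
trajectory's per-frame matched prediction ID differs from the one it was
last matched to (gaps ignored), with per-frame matching at IOU ≥ 0.5.

*HOTA.*  For each α in 0.05, 0.10, …, 0.95: per-frame Hungarian matching
maximizes total IOU among pairs with IOU ≥ α, giving TP/FP/FN and
`DetA = TP/(TP+FP+FN)`.  For each TP c = (g, p), `TPA(c)` counts TPs
linking the same pair over the sequence, `FNA(c) = |g| − TPA`,
`FPA(c) = |p| − TPA`; `AssRe` and `AssPr` are the TP-means of
`TPA/(TPA+FNA)` and `TPA/(TPA+FPA)`, and

    AssA = AssRe·AssPr / (AssRe + AssPr − AssRe·AssPr),
    HOTA_α = √(DetA_α · AssA_α),

with final scores the means over the α grid.  One deliberate choice: AssA
is *derived* from the aggregated AssRe/AssPr through the displayed
identity, so the identity holds exactly at every α.  (An alternative
convention averages per-TP Jaccard scores directly, for which the identity
holds per TP but not after averaging; the two agree on the toy sequences
the test suite enumerates.)  The simplified per-frame matching optimizes
IOU only, which is adequate at the problem sizes the package evaluates.

## The synthetic field simulator

The simulator emulates the acquisition geometry the tracker targets: a
planar field of `n_lanes` parallel lanes with fixed ground positions, a
camera window translating along the lane direction under a
piecewise-constant velocity profile, and detection degradation.

Defaults map the reference field geometry to pixels: an 810 × 1080 cropped
image; in-lane spacing 300 px (0.3–0.35 m seen from 1.5 m height), lane
separation 270 px (0.3 m); camera step ~6 px/frame (0.35–0.45 m/s at
30 Hz); box sizes ~100 px.  No camera intrinsics are modeled — the
metric-to-pixel mapping is a configuration choice and every quantity is
exposed.  Field layout randomness (spacing jitter, size jitter) and
detection noise (center/size jitter, miss probability, Poisson false
positives placed uniformly, emulating weed/soil misdetections) carry
separate seeds so one field can be replayed under many noise draws.
Ground truth contains every plant with at least 25% of its box area inside
the window, clipped to the window, under a persistent lane-major ID.
Motion is applied between frames: frame t sits at the cumulative offset of
frames 1..t−1, so a forward segment followed by its mirror retraces the
same window positions.

**What the simulator does not emulate** — and therefore what passing tests
do *not* show about real data: appearance (no pixels, no detector — misses
are independent Bernoulli rather than correlated with occlusion, blur, or
growth stage), perspective and lens distortion (boxes translate rigidly;
real nadir imagery has mild parallax), curved or converging rows, plant
growth or wilting between passes, lateral camera drift and platform
vibration, and correlated detector failures (e.g. a weed patch generating
persistent false positives at one location).  Results on the benchmark
demonstrate the *association logic* under the stated geometry, not
detector robustness.

## Benchmark scenarios and problem sizes

The frozen benchmark (`rowtrack.scenarios`) uses a denser field than the
simulator default — 2 lanes × 20 plants at 100 px spacing, 80 px boxes —
so that a 200-frame pass at 6 px/frame sweeps every plant through the
view; candidate-window radii are sized from the visible-plant count
(⌈(1080+80)/100⌉+2 = 14).  Three regimes: *straight* (200 frames),
*back-and-forth* (200 + 200 frames; every plant exits and re-enters), and
*noisy back-and-forth* (center σ = 2 px, size σ = 2 px, 5% misses, ten
noise seeds).  The throughput check tracks a 1,000-frame sequence over
2 × 60 plants.  These sizes keep the full suite within a few minutes on a
single CPU while exercising every code path, including re-identification
of every plant in the field.

With a 5% miss rate, IDF1 is bounded near 0.974 even with perfect
association (every missed detection is an identity false negative), which
is why the noisy-regime medians sit just below that ceiling.

## Numerical and degenerate-input choices

- All pixel coordinates are continuous, origin top-left, y downward; file
  corner offsets are taken as exact reals with no 0/1-based adjustment.
- `fit_center_line` requires ≥ 2 distinct `cy` values; an all-horizontal
  layout is a degenerate-geometry error (the lane columns cannot be
  parameterized as x(y)).
- A residual of exactly zero in the two-lane split takes the lane of the
  nearest nonzero-residual detection; `cy` ties break by `cx` — both
  measure-zero cases needing a deterministic rule.
- Frames with fewer than two detections skip geometry and fall back to
  IOU-only association without minting; empty frames advance predictions.
- Tracks unseen for more than `patience = 3` frames are declared out of
  view and their predictions frozen (extrapolating through long gaps is
  meaningless; frozen entries contribute zero IOU and compete on features
  and position only).  A re-entering plant's filter is re-initialized at
  the observed box.
- Assignment ties break toward the lowest detection index; all minting is
  in deterministic lane/entry order.  There is no randomness anywhere in
  the tracking path: identical inputs give byte-identical output files.
- Detection confidences below `min_conf = 0.3` are dropped before
  association.
- Stored features are replaced by the latest clean extraction by default;
  exponential averaging is available (`feature_ema`) but off, as features
  of ground-fixed plants are time-invariant and the freshest clean
  extraction reflects the current detector behavior best.

## Known limitations

- The two thresholds (`tau_feat`, `tau_final`, both 0.5 in
  spacing-normalized units) and the window radii have no published values;
  the defaults are package choices, exposed in configuration.
- Re-identification relies on planting-order adjacency; a field section
  where *all* plants of a lane are missed for many frames while the camera
  moves (so no anchor survives) would defer detections until an anchor
  reappears.
- The ordinal-space candidate window generalizes the single-lane raw-ID
  window; on genuinely single-lane data with gaps in ID numbering the two
  modes can differ.
- MOTA/MOTP are intentionally not implemented; the identity family and
  HOTA are the relevant scores for spray-exactly-once applications.
- The IOU-only ablation is a deliberately minimal SORT-like baseline (no
  track-confirmation heuristics, no aspect-ratio state); it is meant to
  isolate the contribution of the feature/library mechanism, not to
  reproduce any specific published tracker.
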