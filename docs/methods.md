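# Methods

This note documents the models, parameter choices and numerical decisions
behind `phagotrack`, and what the synthetic benchmark does and does not
establish about real data.

## Pre-processing

Recordings arrive as one 3D grid per time point, indexed (row y, column x,
slice z); all coordinates in the package are 0-based (x, y, z) in pixels of
the grid they were measured on, and outputs record the grid via the run
manifest. An optional 2×2 in-plane reduction (on by default) averages each
group of four contiguous voxels per slice: it halves the in-plane
resolution, doubles the in-plane voxel size, halves additive noise
amplitude, and leaves slice count untouched. Odd trailing rows/columns are
cropped so blocks stay contiguous.

Channels are classified from their pooled histogram: a channel is called
fluorescent when ≥ 85% of its voxels lie in the lowest quarter of its
observed dynamic range (sparse bright cells on a dark background), else
DIC. Computing the statistic on the observed range makes it invariant to
global intensity rescaling. Both the 25% range fraction and the 0.85
cutoff are configurable; the classification can be overridden per channel.

## Segmentation

Foreground is a double-hysteresis threshold: connected components of
{v ≥ low} (26-connectivity by default; 6 available) are kept when they
contain a voxel ≥ high. `hysteresis_mask(v, t, t)` reduces exactly to
simple thresholding, and the mask is monotone in both thresholds.

The two thresholds are the boundaries of a 3-class Otsu partition
(exhaustive two-threshold between-class-variance maximisation on a 256-bin
histogram, pooled over the whole recording by default so thresholds are
consistent in time; per-time-point mode available). One histogram detail
matters: in sparse-foreground fluorescence volumes the background holds
> 99% of the voxels, and a count-weighted partition then maximises
between-class variance by subdividing the background noise bulge rather
than isolating the minority cell class. The partition is therefore applied
to log(1 + count) histogram weights by default, which rebalances the
classes while leaving well-balanced histograms essentially unchanged;
`histogram_weighting="counts"` restores the classic behaviour.

Volume outliers — objects above mean + kσ (k = 3) of the volume
distribution pooled over all objects at all time points — are taken to be
two touching cells. They are eroded with a 3×3×3 element (3×3×1 when the
z step dwarfs the pixel size) until they separate, then every original
voxel is reassigned to the nearest surviving piece, so total foreground
volume is conserved exactly. A convex object that erodes away before
separating is left intact and flagged `unsplittable`.

## Tracking

The keyhole predicts a cell's landing from its last displacement **v**:
a wedge of half-angle 30° about the prediction x(t) + **v**, reaching
3|**v**| from the current position, plus the complementary 300° truncated
sphere of radius |**v**|. The wedge and sphere multipliers (3×, 1×) and
angles are configurable. Links are assigned greedily in ascending distance
to the predicted landing point, ties broken by node id, so tracking is
deterministic.

Three data-driven radii are resolved from the median equivalent-sphere
object diameter d:

* `first_link_radius` = 3d — the plain sphere used when a track has no
  motion history or its previous displacement is below the idle tolerance
  (0.5 px);
* `gap_roi_radius` = 2d — the region of interest for gap bridging and for
  the "neighbouring track" test in collision detection;
* `min_radius` = 1d — a floor on the keyhole extent. Segmentation
  centroids jitter by a fraction of the cell size, so a keyhole smaller
  than that uncertainty would reject genuine links of slow, smoothly
  moving cells whenever one step is marginally longer than the previous
  one. The floor is a measurement-noise statement, not a motion model
  change; set `min_radius=0` for the bare geometry.

Backward validation rebuilds the keyhole from the two later nodes pointing
backward and cuts links whose earlier node falls outside; by default every
link is tested (first-link-only mode available), and severed head segments
become their own tracks. Gap bridging inserts an interpolated node
(midpoint centroid, mean volume, flagged `interpolated`) when a track ends
at t−1 and another starts at t+1 within `gap_roi_radius`; only single-frame
gaps are bridged by default. Both the nearest-endpoint tie-break and every
bridge are logged.

Collisions are declared when a track's volume jumps by ≥ 1.5×
(`collision_volume_ratio`; "increases considerably" is inherently a
judgement call, so the value is configurable and recorded in the manifest)
while a neighbouring track terminated in the previous frame within
`gap_roi_radius`. The merged object is re-split frame by frame with a
watershed on its inverted distance transform, seeded at the colliding
tracks' previous centroids, each frame's split centroids seeding the next.
The watershed uses compactness 0.5: on dumbbell-shaped merges the cut
still falls on the distance-transform neck, while on heavily overlapping
near-spherical cells — whose inverted distance transform has a single
minimum and no ridge — the compactness term regularises the partition
toward the nearest-seed split instead of letting one basin flood the whole
object. Because crossing cells can merge, separate and re-merge, collision
resolution iterates: detect the earliest unhandled merge, split its
frames, rebuild the node table, re-link (with backward validation and gap
bridging), and repeat to a fixed cap (50). Watershed failures (fewer
pieces than seeds) leave the object merged and are logged. Division
events (the inverse signature) are detected and logged; the re-linking
pass routes the separated objects. Total foreground volume is conserved
by construction since the watershed partitions the object's own voxels.

Identity through a symmetric collision is resolved by proximity: two cells
that pass straight through each other are geometrically indistinguishable
from two cells that bounce, and the keyhole prediction decides. Editing
(`delete`, `break`, `merge`) exists precisely for the cases where a human
knows better; every edit appends to an audit log.

## Kinematics

The wound frame maps a user rectangle and side (or explicit angle) to a
unit axis **c** toward the wound and **r** = **c** rotated +90° in image
coordinates (y down). Oriented and lateral distances are in-plane
projections on **c** and **r**; z enters only the absolute distance, so
oriented² + lateral² + z² = absolute² holds exactly. The effective
velocity is oriented/absolute — the cosine of the angle between the
displacement and **c**, the unique smooth score with anchors +1 (straight
at the wound), 0 (perpendicular), −1 (straight away); a zero step scores 0
by convention.

Per-track metrics divide mean per-step components by the frame interval
and scale by pixel size (µm/min when metadata are present, px/frame
otherwise). The meandering index is start-to-end distance over path
length; it is undefined (reported missing, never 0) for a zero-length
path.

Population measurements: forward ratio counts displacements with effective
velocity > 0.6 over all displacements. The mirrored backward criterion
(< −0.6) is the default for the backward and leave-wound ratios; a
`literal_backward` switch implements the alternative reading (> −0.6),
since the defining inequality's sign is genuinely ambiguous in common
usage and the two readings answer different questions. The idle threshold
is absolute velocity < 0.5 px/frame (configurable). In-wound membership is
centroid-inside-rectangle; "in wound ratio" counts all displacements while
"in wound ratio 2" restricts the denominator to displacements made after
the track first reached the wound; transiting cells are those that enter
and later leave. Ratios with empty denominators are reported as missing,
never as 0.

The volume-vs-position profile keeps migratory tracks (duration > 30
frames and mean speed ≥ 2 px/frame by default — long enough to span the
field, fast enough to exclude cells already parked at the wound), bins
every surviving node by centroid column into 25 adjacent bands of 20
columns, averages volume per band, and normalises by the mean volume of
the contributing nodes so the grand node-weighted mean is 1. An ordinary
least-squares regression of normalised node volume on band index supplies
the slope with a two-sided t-test and r².

## Synthetic benchmark

The generator emulates a wound-response recording: by default 98 time
points of 11 slices of 275×275 pixels containing six cells. Paths cover
the conditions that stress a tracker: a straight run, a sinusoidal
(tortuous) wander, a delayed-activation cell that idles before moving, a
crossing pair whose minimum mutual separation (5 px, mostly in z) is well
under a cell diameter, and a near-stationary dweller. Cells are
anisotropic Gaussians with per-cell orientation (or irregular shapes: an
isotropic Gaussian plus six randomly offset sub-Gaussians), amplitude 250
over a background of 8, in-plane width σ_xy = 3 px, axial width
σ_z = 1.2 slices, frame interval 0.5 min, unit voxels.

Two rendering choices are deliberate physics:

* **Saturation.** Intensities clip at 230, emulating detector saturation
  in bright cell cores. A pure Gaussian peak loses its hysteresis seed as
  soon as the high threshold is rescaled past ~0.7× its peak, so a
  saturating core is what makes segmentation stable under upward threshold
  rescaling — as it is in real recordings, where bright cells routinely
  saturate.
* **Cell class = everything above 5% of the cell's peak** (also the render
  truncation radius, so the noiseless background is exactly flat). The
  cell/background separability of real fluorescence data is limited by the
  dim cell fringes, not the bright cores; including the fringes gives the
  cell class a large internal intensity spread, and the Bhattacharyya
  distance is then dominated by the variance-ratio term rather than the
  mean-separation term. Under this class structure the calibrated noise
  ladder produces an SNR ladder (28.0, 21.8, 17.6, 12.4, 9.4 dB, computed
  as 20·log10 of the ratio of the classes' RMS deviations from their own
  means) with the characteristic large signal-to-background RMS ratios of
  real recordings. A half-maximum class boundary is a one-line
  configuration change (`class_fraction=0.5`) but makes the reference
  BD ladder reachable only at noise levels that swamp the thresholds.

Noise is white Gaussian (variance σ² everywhere) or Poisson + Gaussian
(photon shot noise with the voxel's expectation, plus read noise), clipped
below at 0 — the valid range of intensity data; quantisation to 8 bits
happens only on TIFF export, and all statistics are computed
pre-quantisation. Calibration finds σ by bisection so the *model* BD hits
a target: the model propagates the noiseless per-class value histograms
through exact clipped-normal moments (for the Poisson model, the unclipped
value + σ² variance), so the zero-clip — substantial when the background
mean is a few counts — is accounted for analytically and the empirical BD
of generated voxels lands within ±0.005 of the target at the default
volume (≈ 8×10⁷ voxels). The five default levels target BD = (1.61, 1.25,
1.0, 0.66, 0.45) and are recomputed at call time rather than shipped as
constants. BD is symmetric, non-negative, zero iff the class stats
coincide, and strictly decreasing in added noise.

## Evaluation

D_AG is the mean, over automatic nodes, of the distance to the nearest
gold node at the same time point; D_GA is the mirror image. Nodes at time
points absent from the other set are excluded from the mean and reported
as unmatched counts (medians and per-track breakdowns are also reported).
Node-wise aggregation was chosen over track-wise so that every detection
(and every miss) carries equal weight; spurious tracks inflate D_AG,
missed cells inflate D_GA. The threshold sweep reruns the full pipeline
per threshold fraction (default 0.4–1.4 in steps of 0.1), reducing the
volumes once up front; a failure at one fraction is recorded and the sweep
continues.

## Problem sizes and determinism

The test suite exercises the full-size default benchmark for track
recovery, BD calibration and the threshold sweep (at a reduced fraction
grid of 0.6/1.0/1.4 and 0.4/1.0), and uses a 96-pixel 3-cell variant with
explicitly separated paths for the faster integration tests — the default
path library's fractional layout is designed for the full field and would
cram cells into continuous contact in a small one, which is a different
(and deliberately harder) study condition than these tests target. The
volume-trend experiment uses 3 cells crossing a 520-column field over 80
frames with volume programmed to grow by 0.2% per column, recovered within
20% by the band profile's OLS slope. Everything is seeded; the same input,
configuration and seed reproduce byte-identical node and track tables, and
the run manifest (config + version + seed + per-stage counts + node-table
checksum) suffices to re-execute a run exactly.

## What passing the benchmark does not show

Synthetic cells are smooth blobs with stationary shape and constant
brightness; real phagocytes extend pseudopods, vary in brightness, touch
in clumps of three or more at the wound (multi-way collisions are resolved
pairwise here, and the iteration can leave residual fragments), and real
backgrounds carry autofluorescence structure rather than flat offsets
with white or Poisson noise. The wound rectangle is user-drawn, and
wound-dependent measurements inherit that subjectivity — sensitivity
analysis over rectangle sizes is recommended when comparing experiments.
Tracking assumes a cell does not jump several diameters per frame past a
neighbour; when it does, the editing tools are the remedy.
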