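# phagotrack

Segmentation, tracking and migration analysis of fluorescent phagocytes
(neutrophils, macrophages) in 3D time-lapse microscopy, with a calibrated
synthetic benchmark for validating the whole chain.

## The problem

Wound-response experiments in optically transparent animals (zebrafish
larvae are the canonical model) image GFP-labelled immune cells in 3D over
hundreds of time points. Turning those multi-gigabyte recordings into
biology — how fast cells move, how directly they head for the wound, how
many arrive, whether their volume changes en route — requires segmenting
bright, shape-shifting blobs out of noisy volumes, linking them through
time without swapping identities, and expressing the motion in a coordinate
frame anchored to the wound. `phagotrack` implements that pipeline for
anyone quantifying chemotaxis of fluorescent cells in 3D+t data.

## The methods at its core

* **Double-hysteresis segmentation.** Voxels above a high threshold are
  cell cores; voxels above a low threshold join the foreground only when
  connected to a core (a Schmitt-trigger in space). This avoids both
  background leakage and the shattering of one dim cell into fragments.
  Both thresholds come from a 3-class Otsu partition of the pooled
  intensity histogram and can be rescaled by a fraction *f* for robustness
  analysis. Objects whose volume exceeds the pooled mean + 3σ are assumed
  to be two touching cells and are split by sequential erosion, conserving
  their total volume.

* **Keyhole tracking.** A cell that moved **v** = x(t) − x(t−1) most
  probably lands near x(t) + **v**. The admissible region for the next
  observation is a keyhole: a 60° wedge aimed at that prediction reaching
  3|**v**|, plus the complementary 300° truncated sphere of radius |**v**|
  for direction changes. Ambiguous candidates are assigned greedily by
  distance to the predicted landing point. Post-processing validates each
  link backward in time with the mirrored keyhole, bridges single-frame
  disappearances by interpolation, and resolves collisions — a volume jump
  of ≥1.5× coinciding with a neighbouring track's end — by re-splitting the
  merged object with a seeded watershed and re-tracking. Delete/break/merge
  editing with an audit log supports manual proofreading.

* **Wound-frame kinematics.** A user-drawn wound rectangle defines an axis
  **c** toward the wound and a lateral axis **r**. Each displacement
  decomposes into oriented (·**c**), lateral (·**r**) and z components with
  |d|² = d_c² + d_r² + d_z²; the *effective velocity* d_c/|d| ∈ [−1, 1]
  scores how directly a step heads to the wound. Per-track summaries
  (velocities, meandering index = chord/path) and the full panel of
  population measurements (forward/backward ratios, wound arrivals,
  idle/transit statistics) follow, plus a banded volume-vs-position profile
  with an OLS trend test for volume changes during recruitment.

* **Calibrated synthetic benchmark.** Gaussian-blob cells (anisotropic or
  irregular multi-Gaussian shapes, saturating cores) travel along straight,
  tortuous, delayed and crossing paths over a dark background; white
  Gaussian or Poisson+Gaussian noise is added at levels *calibrated by
  bisection* so the Bhattacharyya distance (BD) between cell and background
  intensity classes,
  BD = ¼ ln(¼(σ₁²/σ₂² + σ₂²/σ₁² + 2)) + ¼ (μ₁−μ₂)²/(σ₁²+σ₂²),
  hits the ladder (1.61, 1.25, 1.0, 0.66, 0.45). Exact paths and volumes
  are exported as a gold standard, and tracking accuracy is scored by the
  pair D_AG (mean distance from automatic nodes to time-matched nearest
  gold nodes — spurious tracks inflate it) and D_GA (the reverse — missed
  cells inflate it).

## Worked example

```python
import phagotrack as pt

spec = pt.SyntheticSpec()                      # 98 t, 11 slices, 275x275, 6 cells
seq, gold = pt.generate_dataset(spec, seed=1)

sigma = pt.calibrate_noise(spec, target_bd=1.61)      # most separable level
noisy = pt.add_noise(seq, "white_gaussian", sigma, seed=2)

config = pt.PipelineConfig(wound=(110, 137, 0, 137), wound_side="right")
bundle = pt.run_pipeline(noisy, config)

report = pt.track_set_distance(bundle.trackset, gold, scale=bundle.scale_to_original)
print(f"noise sigma        : {sigma:.2f}")
print(f"tracks recovered   : {bundle.trackset.n_tracks}")
print(f"D_AG / D_GA (px)   : {report.d_ag:.2f} / {report.d_ga:.2f}")
pop = bundle.population
print(f"velocity (um/min)  : {pop['velocity']:.2f}")
print(f"meandering index   : {pop['meandering_index']:.2f}")
print(f"forward ratio      : {pop['forward_ratio']:.2f}")
print(f"in-wound cells     : {pop['in_wound_neutrophils']}")
```

prints

```
noise sigma        : 1.94
tracks recovered   : 6
D_AG / D_GA (px)   : 0.72 / 0.72
velocity (um/min)  : 4.36
meandering index   : 0.93
forward ratio      : 0.89
in-wound cells     : 6
```

All six synthetic cells are recovered as uninterrupted tracks whose
centroids sit within a fraction of a pixel of the ground truth (D_AG and
D_GA are means over every node, in original-grid pixels). The population
moves fast and straight (meandering index near 1, 89% of displacements
with effective velocity > 0.6), and every cell reaches the wound rectangle
— exactly what the benchmark's paths program.

The same stages are available from the shell:

```bash
phagotrack synth --out bench --seed 1 --noise-level 1
phagotrack run bench/volumes --wound 110,137,0,137 --out results
phagotrack validate bench/volumes --gold bench/gold_standard.csv --sweep --out sweep
phagotrack edit --nodes results/nodes.csv --tracks results/tracks.json \
    --action break --track 3 --at 42 --out edited
```

Real recordings are read from per-time-point folders of slice TIFFs, from
multi-page TIFFs, or from serialized `.npy` grids (`--layout`, or automatic
detection).

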