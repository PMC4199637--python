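# embryoquant

Quantification pipeline for the imaging assays used to phenotype zebrafish
embryos lacking Optineurin: saltatory axonal vesicle trafficking, pigment-cell
shape, dying-cell counts, and neural-crest stream widths, tied together by a
shared two-group statistics layer. A seeded synthetic-data generator with
analytic ground truth makes every stage testable without any microscope data.

It is intended for researchers quantifying time-lapse and confocal imaging of
embryos, and for anyone who wants a reproducible, scriptable re-implementation
of these common manual measurement protocols.

## What it computes

**Vesicle trafficking.** Fluorescent dextran puncta trafficked through spinal
axons move in a run-and-pause (saltatory) regime. From time-lapse stacks the
pipeline detects bright puncta per frame, compensates stage drift with
stationary embryo landmarks, links detections into trajectories (greedy
nearest-neighbour), and excludes tracks that are static, leave the axon, or do
not traffic anteriorly. A *pause* is a maximal run of consecutive inter-frame
displacements strictly below θ = 0.5 µm (at a 5 s frame interval; both are
configuration, not constants). Per punctum it reports

- overall speed = path length / total time (µm/s),
- moving speed = path length over non-pause intervals / non-pause time,
- % of time paused, and per-pause durations (s),
- a trailing 15 s rolling-speed trace.

**Cell shape.** Segmented cells are scored with the isoperimetric quotient
IQ = 4πA/L² (1 for a perfect circle, lower for cells with more filopodia,
since boundary grows faster than area). Perimeter L comes from a subpixel
boundary reconstruction of the region contour; area A from the pixel count.
Only whole, isolated cells are kept (border, area-range and isolation
filters). Neural-crest stream widths are measured as the anterior–posterior
extent of each stream mask, averaged over the 6 most anterior streams per
embryo.

**Cell death.** Labeled dying cells are counted on maximum-projected z-stacks
restricted to user-supplied anatomical ROI masks (head, trunk, …); a spot's
rounded centroid decides ROI membership, so counts are additive over disjoint
ROIs.

**Statistics.** Every comparison is mean ± SEM per group with a two-sample
pooled-variance Student's t test (Welch behind a flag), annotated
`*` for p ≤ 0.05 and `**` for p ≤ 0.01. No multiple-testing correction is
applied.

## Worked example

Simulate two groups of puncta with the run/pause motion model — 26 wild-type
puncta at 45% stationary pause occupancy versus 22 mutant puncta at 25% —
and compare the four trafficking metrics:

```python
import numpy as np
from embryoquant import synthetic as sy
from embryoquant.trafficking import trajectory_stats, group_trafficking_summary

wt  = sy.MotionParams(run_dwell_mean=27.5, pause_dwell_mean=22.5, n_frames=200)
mut = sy.MotionParams(run_dwell_mean=37.5, pause_dwell_mean=12.5, n_frames=200)
rng = np.random.default_rng(0)
stats_wt  = [trajectory_stats(sy.simulate_trajectory(wt,  int(rng.integers(2**31)))[0])
             for _ in range(26)]
stats_mut = [trajectory_stats(sy.simulate_trajectory(mut, int(rng.integers(2**31)))[0])
             for _ in range(22)]
for metric, c in group_trafficking_summary({"wt": stats_wt, "mut": stats_mut}).items():
    print(f"{metric:>14}: wt {c.mean_a:6.3f} ± {c.sem_a:.3f} (n={c.n_a})  "
          f"mut {c.mean_b:6.3f} ± {c.sem_b:.3f} (n={c.n_b})  p={c.p:.3g} {c.stars}")
```

prints

```
 overall_speed: wt  0.135 ± 0.003 (n=26)  mut  0.184 ± 0.002 (n=22)  p=2.4e-17 **
  moving_speed: wt  0.240 ± 0.000 (n=26)  mut  0.240 ± 0.000 (n=22)  p=5.77e-17 **
    pct_paused: wt 45.980 ± 1.299 (n=26)  mut 24.783 ± 0.802 (n=22)  p=2.31e-17 **
pause_duration: wt 22.192 ± 0.850 (n=536)  mut 13.232 ± 0.507 (n=410)  p=1.81e-16 **
```

Both groups run at 0.24 µm/s when moving, so the moving-speed means agree to
three decimals (the tiny SEMs make even that difference "significant" — a
reminder that the per-punctum unit of replication matters); the wild-type
group pauses almost twice as much, which drags its overall speed down and is
picked up by the %-paused and pause-duration comparisons.

A full shell workflow is available through the `embryoquant` command
(`simulate`, `track`, `traffic`, `shapes`, `count`, `compare`); each
subcommand is a thin wrapper over the library and reads/writes TIFF and tidy
CSV.

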