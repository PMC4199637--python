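# Methods

This note documents the models, estimators and design choices behind
embryoquant, and what the synthetic-data tests do and do not establish about
real microscope data.

## Run-and-pause motion model

Saltatory vesicle transport is modelled as a two-state hidden Markov chain
(run / pause) observed at the acquisition interval Δt (default 5 s, matching
the time-lapse movies the pipeline targets; a configuration key, not a
constant). Dwell times in each state are geometric in frame units with means
`run_dwell_mean` and `pause_dwell_mean` (seconds) — the memoryless choice is
the simplest model consistent with saltatory phenomenology at the sampling
resolution. The per-interval leave probability is `min(1, Δt/dwell_mean)`,
so dwell means shorter than one frame are clamped to a one-frame mean; a
dwell mean of zero disables the state entirely (degenerate always-run /
always-pause limits used by the tests). The chain starts in its stationary
distribution, whose pause occupancy is

    p_pause = pause_dwell_mean / (pause_dwell_mean + run_dwell_mean)

(for dwell means ≥ Δt). During a run interval the punctum steps
`run_speed·Δt` along the anterior axis (+x in scene coordinates; "anterior to
the left" in publication figures is a display convention), anteriorly with
probability `anterior_bias`. During a pause it takes independent
N(0, `pause_jitter_sd`²) steps per coordinate (default 0.05 µm), emulating
localisation noise and residual wobble.

Default conditions: Δt = 5 s, 0.24 µm/s run speed (1.2 µm per frame, safely
above the 0.5 µm pause threshold), 200–240 frames (≈ 20 min of imaging),
0.2 µm/pixel (a 50 µm field over 250 px), trajectory groups of ~25 puncta —
comparable to the 26 vs 22 puncta analysed in the assay this emulates.

## Rendering and what it omits

Time-lapse frames are sums of isotropic Gaussian spots (puncta and brighter
stationary fiducial landmarks), a faint axon polyline, rigid stage drift
(everything translates by `drift_per_frame·k` in frame k) and additive
Gaussian noise clipped at zero. Star-shaped pigment cells are disk-body
polygons (64 vertices) with trapezoidal radial filopodia; the finite tip
width (tip half-angle = half the 0.18 rad base half-angle) keeps spikes
faithfully rasterisable and matches the finite width of real filopodia.
Spot-count scenes place Gaussian spots on pixel centres inside/outside a
binary ROI mask with a minimum separation.

Not modelled: photobleaching, z-drift, realistic PSFs, autofluorescence,
crossing trajectories, touching cells. Passing tests therefore demonstrate
correctness of the measurement algorithms under known geometry and noise,
not robustness to every artefact of live imaging; on real data the detection
thresholds, separation, and area-range parameters must be set per dataset.

## Tracking

Detection: local maxima above `min_intensity` separated by at least
`min_separation` px (brighter peak wins; equal ties go to lower (y, x)),
refined by intensity-weighted centroid in a 5×5 window. An optional Gaussian
prefilter (`smooth_sigma`) is essential on noisy images and lowers peak
values, so the threshold refers to the filtered image. Coordinates are
pixel-centred, 0-based, x = column, y = row, stated in every CSV header.

Drift: each fiducial landmark is followed frame-to-frame (brightest pixel
within a search radius, centroid-refined); drift is the mean displacement of
all fiducials relative to frame 0. A fiducial whose peak falls below
`min_intensity` raises an error naming the frame rather than silently
tracking noise.

Linking is greedy nearest-neighbour with a hard step limit
(`max_step_px` per frame, scaled by gap length), optional gap bridging up to
`max_gap` frames with linearly interpolated, flagged positions. Greedy
assignment is adequate for the sparse, non-crossing tracks this assay
produces; crossing-track disambiguation is explicitly out of scope.

Exclusion rules (all evaluated, reasons logged, order-independent):
*static* — net start→end displacement < 1.0 µm (2× the pause threshold; the
protocol gives no number, so this is config-exposed, and "did not move" is
judged on net, not maximum, displacement); *off-axon* — any point farther
than 3.0 µm (config) from the axon polyline; *non-anterior* — net
displacement along the anterior axis ≤ 0.

## Trafficking statistics

Per-interval displacements are Euclidean distances between consecutive
drift-corrected positions × scale. A pause is a maximal run of intervals
with displacement strictly below θ = 0.5 µm — a displacement of exactly θ
counts as moving (the verbal rule "less than θ … more than θ" leaves
equality ambiguous; it is resolved as non-pause). Speeds use path length,
not net displacement. Gap-bridged intervals count toward time with their
interpolated (evenly split) displacement and stay flagged. A pause touching
the series boundary is still a pause. Conservation holds exactly:
paused + moving time = total time, and pct_paused = 100·Σdurations/total.

Metrics are computed per punctum and compared across puncta (speeds and
%-paused one value per punctum; pause durations one value per pause). The
alternative pooled-over-intervals %-paused is available
(`pooled_pct_paused`) since protocols are often ambiguous about the unit of
averaging. The rolling-speed trace is a trailing mean over `window/Δt`
intervals (default 15 s), undefined for the first `window/Δt − 1` points.

## Shape morphometry

IQ = 4πA/L² with A from the pixel count (× scale²) and L from a subpixel
boundary reconstruction: the outer marching-squares contour is simplified by
Douglas–Peucker (0.7 px), a total-least-squares line is fit to the contour
points of each simplified segment, and adjacent lines are intersected to
place corners — this extrapolates spike apexes that rasterisation blunts
(intersections displaced > 3 px fall back to the raster corner). This
estimator was chosen over multi-direction (Crofton) and weighted
boundary-pixel estimators after direct measurement on the star-cell
generator: both show orientation-dependent IQ bias approaching 10% on
straight filopodia edges, while the reconstruction stays within ~5% of the
analytic polygon IQ at a 30 px body radius (shrinking with size). The bias
can push IQ slightly above 1 on near-circular rasters (ε ≈ 0.05 documented
bound); regions a few pixels across fall back to raw contour length and are
not meaningfully scored.

Segmentation is a global threshold (user value or Otsu's method for "auto";
the original protocol's interactive threshold is not recoverable, so "auto"
is a stand-in, not a claim of equivalence) with 8-connected labelling.
"Whole, isolated cells" is operationalised as: not touching the image
border, inside a configurable area range, and with no other region within a
3 px dilation.

Stream widths: each stream mask's extent along the anterior–posterior axis
× scale; streams ordered by their anterior edge; the per-embryo summary is
the mean over the 6 most anterior (an error, naming the count, if fewer).

## Counting and statistics

Counting runs the shared spot detector on the maximum projection and keeps
detections whose rounded centroid lies inside the ROI mask — centroid
membership makes counts exactly additive over disjoint masks. Whether
overlapping projected spots merge is governed by `min_separation`.

The statistics layer is the classical pooled-variance two-sample Student's
t test (df = nA+nB−2, two-sided), mean ± SEM (sd with n−1 denominator over
√n), stars `*` for p ≤ 0.05 and `**` for p ≤ 0.01. Welch's test is behind a
flag; pooled is the default because the emulated protocol specifies plain
"Student's t test". Zero pooled variance with equal means returns t = 0,
p = 1; with unequal means it is an error (the statistic is unbounded). No
multiple-testing correction is applied, and the output records that.

## Problem sizes used in tests

The suite keeps simulations at desk scale: 30–240 frame trajectories,
448²–512² px rendered images, 25 puncta per group × 100 replicates for the
power check, 2,000 H0 draws for type-I calibration, 1,000 random step series
for the pause-rule oracle. These sizes give Monte-Carlo margins well inside
the asserted tolerances (e.g. occupancy ±0.05 at ≥10⁴ intervals).

## Known limitations

Greedy linking misassigns crossing tracks; the drift model is rigid
translation only; Otsu thresholding assumes a bimodal histogram; the IQ
estimator's 5% accuracy bound is for regions ≥ ~30 px radius; per-embryo
(nested) variance structure is not modelled — both puncta- and embryo-level
units are supported for comparison, but no mixed model is provided.
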