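# Methods

## Grid geometry

The grading grid partitions a disc into cells of identical area: a central
circular cell of radius r₀ and rings j = 1..n of radial width 2·r₀, with
ring j divided into 8·j sectors of equal angular width. The sector area is
π·((2j+1)² − (2j−1)²)·r₀²/(8j) = π·r₀², so the partition is exactly
equal-area and the cell count is 1 + 4·n·(n+1): 289 cells at the default
n = 8, and 121 for the central cell plus rings 1–5. That ring prefix is the
only one with 121 cells, which is why it is used as the central region
approximating the ETDRS seven standard fields; the 8·j sector counts with
ring width 2·r₀ are likewise the unique equal-area concentric layout
producing both 289 and 121.

Conventions fixed for reproducibility: grid coordinates are y-up with
angles counterclockwise from the fovea→disc axis; sector 0 starts at angle
0; every cell is half-open in radius and angle, so each point belongs to at
most one cell and the cells tile the disc. r₀ = 1 internally — physical
units enter only through the landmark transform and the millimetre
calibration.

## Landmark standardization

From the fovea f and disc center o (pixel coordinates, x right / y down,
pixel centers at integer coordinates) the transform is the proper
similarity that maps f to the origin and o to (0.095·D, 0), D the grid
diameter: translation by −f, y negation (so counterclockwise matches the
displayed image), rotation by −atan2(−(o−f)ᵧ, (o−f)ₓ) and scale
0.095·D/|o−f|. The disc always lands on the positive axis regardless of
laterality; no mirroring is applied, so left/right-eye sector identities
are anatomical mirror images (recorded as metadata, not resolved).
Coincident landmarks raise a typed error.

Quantitative statistics never resample pixels: the grid is transformed into
image coordinates and each pixel center is assigned to a cell (the
half-open bounds make per-pixel membership unambiguous). `warp_image`
(bilinear, or nearest for label-like content) exists for presentation only.
No correction of peripheral projection distortion is applied; peripheral
cells therefore cover more true retinal surface than central ones, a known
limitation of planar UWF grading.

Millimetre calibration assumes a constant fovea–disc distance of 4.76 mm
(SD 0.34 mm, from a large fundus-photography population sample), giving a
grid diameter of 4.76/0.095 ≈ 50.11 mm and ≈ 6.82 mm² per cell at the
defaults.

## Grades, scores and aggregation

Six ordinal grades with fixed scores (1, 0.875, 0.625, 0.375, 0.125, 0)
plus UNGRADABLE. Ungradable cells carry no score: they appear in category
counts but are excluded from perfusion means, matching the convention of
disregarding them in paired analyses. "Perfused" as a category means
exactly the 100% grade; hypoperfused is 51–99%, nonperfused 0–50% — the
only exhaustive reading of the bands consistent with the score map
(nonperfused ⇔ score ≤ 0.375). Region means are reported as percent
hypoperfusion = 100·(1 − mean score); a region with no gradable cell yields
an explicitly flagged undefined summary rather than NaN.

Per-image graded-cell domains are session-defined: a session may exclude
cells (e.g. off the captured field) via `excluded_cells` instead of the
package hard-coding an exclusion rule. Display percentages round half-up to
whole percent; all computation uses exact counts.

## Agreement statistics

* Descriptives: mean, SD (ddof 1) and Tukey's five-number summary, with
  hinges as medians of the sorted halves including the overall median when
  n is odd.
* Bland–Altman: differences are grader 1 − grader 2 (negative bias means
  grader 2 measured more), limits of agreement = bias ± 1.96·SD of
  differences; plot data (pair mean, difference) is emitted sorted by mean.
* Kendall's tau-b with tie correction, since per-image nonperfusion scores
  tie frequently (healthy eyes cluster at zero). Constant rankings raise a
  typed error.
* Cohen's kappa: κ_w = 1 − Σw·p_obs / Σw·p_exp with disagreement weights
  |i−j|/(K−1) (linear, the default for three ordered categories), their
  square, or the 0/1 indicator. Two labeled variants are always reported:
  three ordinal categories after dropping cells either grader marked
  ungradable (weighted), and four categories including ungradable
  (unweighted, since ungradable is not ordinal). Which variant a study
  means by "weighted kappa" is ambiguous in general, so both are exposed
  and the excluding-ungradable linear-weight variant is the default.
* Confidence intervals: percentile bootstrap resampling whole images with
  replacement (cells of an image move together), default B = 2000, seed
  mandatory. Replicates on which a statistic is undefined are dropped; more
  than 10% of them aborts with an error naming the failure mode, because
  silently absorbed NaNs would bias the replicate distribution.

Degenerate statistics raise typed errors (`UndefinedStatisticError`,
`DegenerateStatisticError`) rather than returning sentinels.

## Synthetic data

Phantoms emulate the features of a UWF angiogram that the pipeline is
sensitive to: a bright recursive branching vessel tree rooted at the disc,
a diffuse capillary background, dark circular nonperfusion blobs (grid
units) that suppress vessel and background signal by a darkness factor,
peripheral wedge occluders emulating eyelash shadows, and landmarks at a
configurable pixel separation (default 90 px in a 1024² image, placing
part of the outer rings off-field as in real ultra-widefield capture) with
optional jitter. Everything is a pure function of (spec, seed).

Ground truth per cell is the fraction of cell area outside all blobs,
computed by integration over a 1501² Cartesian sample of the grid disc in
grid units — independent of the rendered raster, so it serves as a
geometric oracle for the imaging path. Phantoms whose blobs cover more
than 95% of the grid are rejected.

Simulated graders clamp truth + Gaussian noise to [0, 1] and band it at
cut points 0.005/0.255/0.505/0.755/1.0 — midpoints of the printed
integer-percent band edges, half-open upward, with exactly 1.0 mapping to
the fully-perfused grade — then shift by an integer ordinal bias with
clamping. UNGRADABLE is assigned with a base-rate probability only on
cells overlapped by an artifact or containing no visible vessel pixel, the
two triggers the grading protocol defines. A zero-noise, zero-bias grader
reproduces the banded truth exactly (tested).

What phantoms do *not* model: fluorescein transit phases, photorealistic
texture, projection distortion, vessel pathology (microaneurysms,
neovascularization). Passing tests therefore demonstrate correctness of
geometry, bookkeeping and statistics under known ground truth — not
clinical validity of grading on real angiograms.

### Marginal-matched paired data

`marginal_matched_dataset` builds paired per-cell categories whose
per-grader marginal counts are fixed exactly; the joint table is filled
diagonal-first (maximal raw agreement subject to the marginals), then by
ascending ordinal distance. Count differences between graders depend only
on the marginals, so any feasible joint reproduces them.

`marginals_from_percentages` converts printed integer percentages to
counts by half-up rounding. Printed percentages are themselves rounded,
which leaves a few dozen cells of slack per category; when a report also
prints the number of cells removed by the either-grader-ungradable filter,
passing it as `ungradable_union` pins the counts exactly: the grader with
more ungradable cells takes the union (their ungradable set covering the
other's is the minimal-disagreement configuration selected by the
diagonal-first joint), the other keeps the rounded difference, and
nonperfused absorbs the remainder. Every reconciled count is verified to
round back to its printed percentage.

## Problem sizes and numerical choices

* Rasterization checks use a 4000² raster (≈43k pixels per cell), where
  the max/min cell pixel-count ratio is below 1.02; the partition and
  coverage properties are also checked at smaller rasters.
* Bootstrap coverage is assessed with 200 replications of a 50-image ×
  289-cell two-grader study (grader noise SD 0.15, per-image severity
  uniform on [0, 0.6]), B = 300 replicates each, against a simulation-true
  kappa computed by brute force on 10⁶ cells; observed coverage is
  asserted within 95 ± 4 points.
* Monotone degradation of kappa and tau-b with grader noise is averaged
  over 50 seeds at noise SDs {0, 0.08, 0.15, 0.3, 0.6} with common random
  numbers across levels.
* Transform postconditions are tested to 1e-9 relative to the grid
  diameter; kappa equals a literal two-loop evaluation to 1e-12; tau-b
  matches O(n²) pair counting to 1e-12 (floating-point exactness).

## Known limitations

* No automatic fovea/disc detection; landmarks are inputs.
* No projection-distortion correction; peripheral areas are overweighted
  relative to true retinal surface.
* Left-eye images are not mirrored, so sector-level topographies of OD and
  OS eyes are not directly comparable.
* The grading GUI of the original workflow is represented by file-based
  sessions and the paired cell-patch primitive, not an interactive tool.
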