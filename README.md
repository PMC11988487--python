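# perfgrid

Grid-based quantification of retinal hypoperfusion on ultra-widefield
fluorescein angiograms (UWF FA), for researchers who need reproducible,
spatially localized perfusion grading and inter-rater agreement statistics
without freehand outlining.

## The method

An angiogram is standardized to a common frame from two user-supplied
landmarks — the fovea and the center of the optic disc — by a proper
similarity transform (shift Δx/Δy, rotation θ, isotropic scale) that puts
the fovea at the origin, the disc on the positive horizontal axis, and the
fovea–disc distance *d* at 9.5% of the grid diameter *D* (scale = 0.095·*D*/*d*).
Assuming a constant anatomical fovea–disc distance (4.76 ± 0.34 mm), every
grid cell then covers an equivalent retinal area across eyes: the grid
spans 4.76/0.095 ≈ 50.1 mm, about 6.8 mm² per cell.

The grading grid is an equal-area disc partition: a central circular cell of
radius r₀ surrounded by *n* = 8 concentric rings of radial width 2·r₀, ring
*j* split into 8·*j* sectors. Every cell has area π·r₀² exactly, and

    cells(n) = 1 + 4·n·(n+1)   →   289 cells for n = 8

The central cell plus rings 1–5 (121 cells) approximate the ETDRS seven
standard fields; the remaining 168 cells form the peripheral region.

Each cell receives one of six ordinal perfusion grades with scores
1, 0.875, 0.625, 0.375, 0.125, 0 (fully perfused → nonperfused), or is
marked **ungradable** (no visible vessel, or an image artifact such as an
eyelash shadow). Regional perfusion is the mean score over gradable cells,
reported as percent hypoperfusion = 100·(1 − mean score). For categorical
analysis, grades collapse to perfused (100%), hypoperfused (51–99%) and
nonperfused (0–50%).

Two-grader agreement uses cross-tabulation and Cohen's weighted kappa on
cell categories, Kendall's tau-b and Bland–Altman limits of agreement on
per-image percent hypoperfusion, with 95% confidence intervals from an
image-level (cluster) percentile bootstrap.

Because no patient images ship with the package, a synthetic module
generates phantom angiograms (bright vessel tree, dark nonperfusion blobs
with known geometric footprint, peripheral lash-like artifacts) with exact
per-cell ground truth, plus simulated graders with tunable bias, noise and
ungradable propensity.

## Worked example

```python
import numpy as np
from perfgrid import (GraderModel, PhantomSpec, Region, agreement_report,
                      generate_phantom, pair_sessions, region_summary,
                      simulate_grader)

# one phantom eye with three nonperfusion blobs, graded by two noisy graders
phantom = generate_phantom(PhantomSpec(image_size=(384, 384), seed=11,
                                       n_blobs=3, fovea_disc_px=34.0))
g1 = simulate_grader(phantom.truth, GraderModel(noise_sd=0.08, seed=1),
                     phantom.grid, image_id="eye0", grader_id="g1")
g2 = simulate_grader(phantom.truth, GraderModel(noise_sd=0.08, bias=-1, seed=2),
                     phantom.grid, image_id="eye0", grader_id="g2")
for s in (g1, g2):
    rs = region_summary(s, Region.ENTIRE)
    print(f"{s.grader_id}: {rs.percent_hypoperfusion:.1f}% hypoperfusion "
          f"({rs.n_graded} cells graded)")

# agreement across a small 8-image study
pairs = []
rng = np.random.default_rng(0)
for i in range(8):
    ph = generate_phantom(PhantomSpec(image_size=(256, 256), seed=100 + i,
                                      n_blobs=int(rng.integers(0, 6)),
                                      fovea_disc_px=23.0))
    a = simulate_grader(ph.truth, GraderModel(noise_sd=0.08, seed=1000 + i),
                        ph.grid, image_id=f"eye{i}", grader_id="g1")
    b = simulate_grader(ph.truth, GraderModel(noise_sd=0.08, bias=-1, seed=2000 + i),
                        ph.grid, image_id=f"eye{i}", grader_id="g2")
    pairs.append(pair_sessions(a, b))

rep = agreement_report(pairs, Region.ENTIRE, weights="linear", B=500, seed=7)
ci = rep.kappa_excluding_ci
print(f"weighted kappa = {rep.kappa_excluding.kappa:.3f} "
      f"(95% CI {ci.low:.3f}-{ci.high:.3f})")
print(f"tau-b = {rep.tau.tau:.3f}; Bland-Altman bias = {rep.bland_altman.bias:.2f} "
      f"points of percent hypoperfusion")
```

prints

```
g1: 10.6% hypoperfusion (289 cells graded)
g2: 29.7% hypoperfusion (289 cells graded)
weighted kappa = 0.142 (95% CI 0.033-0.235)
tau-b = 0.837; Bland-Altman bias = -18.45 points of percent hypoperfusion
```

Grader 2 carries a one-level pessimistic bias, so it measures nearly three
times the hypoperfusion of grader 1 on the same eye. The negative
Bland–Altman bias says grader 2 reports ~18 points more hypoperfusion per
image; tau-b stays high because a consistent bias preserves the ranking of
eyes, while the cell-level weighted kappa collapses because the graders
rarely assign the same category.

## Command line

`perfgrid` exposes `grid`, `normalize`, `simulate`, `summarize` and
`compare` subcommands (see `perfgrid --help`). Sessions, landmarks and
transforms are plain JSON; grids and reports are CSV; every run writes its
resolved configuration (including seeds) next to its outputs. Exit codes
distinguish validation (2), I/O (3) and statistical-degeneracy (4) errors.

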