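"""Synthetic angiogram phantoms and simulated graders.

No patient images ship with this package; everything downstream is
exercised on phantoms that emulate the salient structure of an
ultra-widefield fluorescein angiogram:

* a bright branching vessel tree radiating from the optic disc on a dark
  background,
* dark nonperfusion blobs that locally suppress vessel signal (with a known
  geometric footprint, so per-cell ground-truth perfusion is available),
* peripheral lash-like occluding bands emulating eyelash shadows and poor
  illumination, and
* fovea/disc landmarks at an anatomically plausible pixel separation with
  optional jitter.

Ground truth per cell is the fraction of the cell's area lying outside all
blobs, computed by fine-grid integration in grid units — independent of the
rendered raster. Simulated graders band a noisy latent perfusion fraction
into the six ordinal levels, optionally shift by an ordinal bias, and mark
cells ungradable where artifacts overlap or no vessel is visible.

:func:`marginal_matched_dataset` builds paired categorical gradings whose
per-grader marginal counts are fixed exactly — the construction used to
reproduce printed two-grader comparison tables, where count differences
depend only on the marginals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from skimage.draw import line_aa

from .grading import (
    GRADABLE_LEVELS,
    Category,
    GradeLevel,
    GradingSession,
    round_half_up,
)
from .grid import CellIndex, GridSpec, locate_array
from .transform import GridTransform, Landmarks, compute_transform

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "save_phantom_bundle",
    "load_phantom_bundle",
    "GraderModel",
    "grade_from_fraction",
    "simulate_grader",
    "CATEGORY_ORDER",
    "marginals_from_percentages",
    "PairedCategoryData",
    "marginal_matched_dataset",
]

#: Band cut points on the latent perfusion fraction. Bands are half-open
#: upward ([0.505, 0.755) -> P51_75 etc.); exactly 1.0 (after clamping)
#: maps to P100. Midpoints between the printed integer-percent band edges.
BAND_EDGES = np.array([0.005, 0.255, 0.505, 0.755, 1.0])


def grade_from_fraction(fraction) -> np.ndarray:
    """Band latent perfusion fractions into the six ordinal levels (0..5)."""
    x = np.asarray(fraction, dtype=np.float64)
    return np.digitize(x, BAND_EDGES, right=False)


# ---------------------------------------------------------------------------
# Phantom images


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic angiogram.

    All randomness derives from ``seed``: the same spec + seed is
    byte-identical. ``blobs`` may pin explicit nonperfusion blobs as
    ``(cx, cy, radius)`` triples in grid units; otherwise ``n_blobs`` blobs
    are placed at random inside the grid.
    """

    image_size: tuple[int, int] = (1024, 1024)
    seed: int = 0
    vessel_density: int = 6  # initial branches per quadrant
    n_blobs: int = 4
    blob_radius_range: tuple[float, float] = (1.5, 3.5)
    blob_darkness: float = 0.25
    artifact_bands: int = 2
    landmark_jitter: float = 0.0
    fovea_disc_px: float = 90.0
    blobs: Optional[tuple[tuple[float, float, float], ...]] = None


@dataclass
class Phantom:
    """A rendered phantom with its landmarks and per-cell ground truth."""

    image: np.ndarray
    landmarks: Landmarks
    grid: GridSpec
    transform: GridTransform
    truth: dict[CellIndex, float]
    blobs: tuple[tuple[float, float, float], ...]
    artifact_mask: np.ndarray
    artifact_cells: frozenset[CellIndex]
    vessel_cells: frozenset[CellIndex]
    spec: PhantomSpec


def _blob_membership(gx, gy, blobs):
    inside = np.zeros(gx.shape, dtype=bool)
    for cx, cy, rad in blobs:
        inside |= (gx - cx) ** 2 + (gy - cy) ** 2 < rad**2
    return inside


def _truth_by_integration(
    grid: GridSpec, blobs, n_samples: int = 1501
) -> tuple[dict[CellIndex, float], float]:
    """Per-cell perfused-area fraction by fine-grid integration (grid units)."""
    R = grid.total_radius
    xs = np.linspace(-R, R, n_samples)
    gx, gy = np.meshgrid(xs, xs)
    ids = locate_array(gx, gy, grid)
    keep = ids >= 0
    ids_k = ids[keep]
    inblob = _blob_membership(gx, gy, blobs)[keep]
    total = np.bincount(ids_k, minlength=grid.n_cells)
    covered = np.bincount(ids_k, weights=inblob, minlength=grid.n_cells)
    frac_covered = covered / np.maximum(total, 1)
    truth = {
        cell: float(1.0 - frac_covered[cell.flat]) for cell in grid.cells()
    }
    overall = float(covered.sum() / total.sum())
    return truth, overall


def _draw_vessel_tree(shape, rng, disc_xy, density):
    """Recursive bright branching tree rooted at the disc center."""
    h, w = shape
    layer = np.zeros(shape, dtype=np.float64)

    def segment(x0, y0, ang, length, depth, intensity):
        x1 = x0 + length * math.cos(ang)
        y1 = y0 + length * math.sin(ang)
        r0c, c0c = int(round(y0)), int(round(x0))
        r1c, c1c = int(round(y1)), int(round(x1))
        rr, cc, val = line_aa(r0c, c0c, r1c, c1c)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.maximum.at(layer, (rr[ok], cc[ok]), val[ok] * intensity)
        if depth <= 0 or length < 6:
            return
        for sign in (-1.0, 1.0):
            segment(
                x1,
                y1,
                ang + sign * rng.uniform(0.15, 0.55),
                length * rng.uniform(0.6, 0.8),
                depth - 1,
                intensity * 0.85,
            )

    n_trunks = max(4, 4 * density)
    for ang in np.linspace(0.0, 2.0 * math.pi, n_trunks, endpoint=False):
        segment(
            disc_xy[0],
            disc_xy[1],
            ang + rng.uniform(-0.2, 0.2),
            rng.uniform(60, 110),
            4,
            1.0,
        )
    return layer


def generate_phantom(spec: PhantomSpec, grid: Optional[GridSpec] = None) -> Phantom:
    """Render a phantom angiogram with known per-cell perfusion truth."""
    if grid is None:
        grid = GridSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    fovea = np.array([w / 2.0, h / 2.0])
    if spec.landmark_jitter > 0:
        fovea = fovea + rng.normal(0.0, spec.landmark_jitter, size=2)
    ang = math.radians(rng.uniform(-15.0, 15.0))
    disc = fovea + spec.fovea_disc_px * np.array([math.cos(ang), math.sin(ang)])
    landmarks = Landmarks(fovea=tuple(fovea), disc_center=tuple(disc), laterality="OD")
    transform = compute_transform(landmarks, grid)

    R = grid.total_radius
    if spec.blobs is not None:
        blobs = tuple(tuple(map(float, b)) for b in spec.blobs)
    else:
        blobs = []
        for _ in range(spec.n_blobs):
            rad = rng.uniform(*spec.blob_radius_range)
            rho = rng.uniform(0.0, 0.8 * R)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            blobs.append((rho * math.cos(phi), rho * math.sin(phi), rad))
        blobs = tuple(blobs)
    truth, covered = _truth_by_integration(grid, blobs)
    if covered > 0.95:
        raise ValueError(
            f"nonperfusion blobs cover {100 * covered:.1f}% of the grid (> 95%); "
            "rejected as unrenderable"
        )

    # grid coordinates of every pixel center
    cc, rr = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    g = transform.apply(np.stack([cc, rr], axis=-1))
    gx, gy = g[..., 0], g[..., 1]
    grad = np.hypot(gx, gy)
    in_grid = grad < R
    inblob = _blob_membership(gx, gy, blobs)

    vessels = _draw_vessel_tree((h, w), rng, (float(disc[0]), float(disc[1])), spec.vessel_density)
    vessels = vessels * np.where(inblob, spec.blob_darkness, 1.0)

    # diffuse capillary background, suppressed inside blobs
    background = 12.0 + 28.0 * in_grid * np.where(inblob, spec.blob_darkness, 1.0)
    background += rng.normal(0.0, 3.0, size=(h, w))

    # peripheral lash-like occluders (dark wedges in the outer grid)
    artifact_mask = np.zeros((h, w), dtype=bool)
    theta_pix = np.mod(np.arctan2(gy, gx), 2.0 * math.pi)
    for _ in range(spec.artifact_bands):
        t0 = rng.uniform(0.0, 2.0 * math.pi)
        width = rng.uniform(0.15, 0.40)
        band = (grad > 0.62 * R) & (np.mod(theta_pix - t0, 2.0 * math.pi) < width)
        artifact_mask |= band

    image = background + 190.0 * vessels
    image[artifact_mask] *= 0.05
    image = np.clip(image, 0, 255).astype(np.uint8)

    # per-cell bookkeeping for grader simulation
    ids = locate_array(gx, gy, grid)
    keep = ids >= 0
    ids_k = ids[keep]
    vessel_visible = (vessels > 0.3) & ~artifact_mask
    vessel_counts = np.bincount(ids_k, weights=vessel_visible[keep], minlength=grid.n_cells)
    artifact_counts = np.bincount(ids_k, weights=artifact_mask[keep], minlength=grid.n_cells)
    vessel_cells = frozenset(c for c in grid.cells() if vessel_counts[c.flat] > 0)
    artifact_cells = frozenset(c for c in grid.cells() if artifact_counts[c.flat] > 0)

    return Phantom(
        image=image,
        landmarks=landmarks,
        grid=grid,
        transform=transform,
        truth=truth,
        blobs=blobs,
        artifact_mask=artifact_mask,
        artifact_cells=artifact_cells,
        vessel_cells=vessel_cells,
        spec=spec,
    )


def save_phantom_bundle(phantom: Phantom, directory) -> None:
    """Write a phantom as image (PNG) + landmarks (JSON) + truth (CSV) + spec (JSON)."""
    from pathlib import Path

    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(phantom.image).save(directory / "image.png")
    phantom.landmarks.to_json(directory / "landmarks.json", image="image.png")
    rows = [
        {"ring": c.ring, "sector": c.sector, "fraction": phantom.truth[c]}
        for c in phantom.grid.cells()
    ]
    pd.DataFrame(rows).to_csv(directory / "truth.csv", index=False)
    with open(directory / "spec.json", "w") as fh:
        json.dump(asdict(phantom.spec), fh, indent=2)
        fh.write("\n")


def load_phantom_bundle(directory) -> Phantom:
    """Regenerate a phantom from its saved spec (generation is deterministic)."""
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "spec.json") as fh:
        raw = json.load(fh)
    raw["image_size"] = tuple(raw["image_size"])
    raw["blob_radius_range"] = tuple(raw["blob_radius_range"])
    if raw.get("blobs") is not None:
        raw["blobs"] = tuple(tuple(b) for b in raw["blobs"])
    return generate_phantom(PhantomSpec(**raw))


# ---------------------------------------------------------------------------
# Simulated graders


@dataclass(frozen=True)
class GraderModel:
    """Stochastic model of one grader.

    ``bias`` shifts the banded grade by whole ordinal levels (positive =
    toward perfused), ``noise_sd`` perturbs the latent perfusion fraction
    before banding, and ``ungradable_base_rate`` is the probability of an
    UNGRADABLE call on cells where an artifact overlaps or no vessel is
    visible. A zero-noise, zero-bias model reproduces the ground-truth
    bands exactly.
    """

    bias: int = 0
    noise_sd: float = 0.0
    ungradable_base_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if not (0.0 <= self.ungradable_base_rate <= 1.0):
            raise ValueError("ungradable_base_rate must be in [0, 1]")


def simulate_grader(
    truth: Mapping[CellIndex, float],
    model: GraderModel,
    grid: GridSpec,
    image_id: str = "phantom",
    grader_id: str = "sim",
    artifact_cells: Optional[frozenset] = None,
    visible_vessel_cells: Optional[frozenset] = None,
    excluded_cells: Optional[frozenset] = None,
) -> GradingSession:
    """Produce a grading session from ground truth and a grader model.

    Cells are processed in flat-id order; all randomness comes from
    ``model.seed`` so a model grades identically on identical truth.
    """
    artifact_cells = artifact_cells or frozenset()
    visible = visible_vessel_cells  # None means every cell shows a vessel
    excluded = frozenset(excluded_cells or frozenset())
    cells = [c for c in grid.cells() if c in truth and c not in excluded]
    frac = np.array([truth[c] for c in cells], dtype=np.float64)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("truth fractions must lie in [0, 1]")
    rng = np.random.default_rng(model.seed)
    latent = frac
    if model.noise_sd > 0:
        latent = np.clip(frac + rng.normal(0.0, model.noise_sd, size=frac.size), 0.0, 1.0)
    idx = np.clip(grade_from_fraction(latent) + model.bias, 0, 5)
    u = rng.uniform(size=frac.size)
    grades = {}
    for i, cell in enumerate(cells):
        candidate = cell in artifact_cells or (visible is not None and cell not in visible)
        if candidate and u[i] < model.ungradable_base_rate:
            grades[cell] = GradeLevel.UNGRADABLE
        else:
            grades[cell] = GRADABLE_LEVELS[int(idx[i])]
    return GradingSession(
        image_id=image_id,
        grader_id=grader_id,
        grid=grid,
        grades=grades,
        excluded_cells=excluded,
    )


# ---------------------------------------------------------------------------
# Marginal-matched paired categorical data


CATEGORY_ORDER = (
    Category.PERFUSED,
    Category.HYPOPERFUSED,
    Category.NONPERFUSED,
    Category.UNGRADABLE,
)


def marginals_from_percentages(
    total: int,
    pct_1: Mapping[Category, float],
    pct_2: Mapping[Category, float],
    ungradable_union: Optional[int] = None,
) -> tuple[dict[Category, int], dict[Category, int]]:
    """Convert printed per-grader category percentages to exact counts.

    Plain conversion rounds ``pct * total / 100`` half-up and requires the
    counts to sum to ``total``. Printed percentages are themselves rounded,
    which leaves a few dozen cells of slack; when the report also prints the
    number of cells removed by the either-grader-ungradable filter, passing
    it as ``ungradable_union`` pins the counts exactly: the grader with more
    ungradable cells gets ``ungradable_union`` (their ungradable set covers
    the other's), the other keeps the rounded difference, perfused and
    hypoperfused counts stay at their rounded values and nonperfused absorbs
    the remainder. Every reconciled count is checked to round back to its
    printed percentage.
    """
    def rounded(pct):
        counts = {c: round_half_up(pct[c] * total / 100.0) for c in CATEGORY_ORDER}
        if sum(counts.values()) != total:
            raise ValueError(
                f"percentages {dict(pct)} are infeasible: rounded counts sum to "
                f"{sum(counts.values())}, not {total}"
            )
        return counts

    c1, c2 = rounded(pct_1), rounded(pct_2)
    if ungradable_union is None:
        return c1, c2
    u = Category.UNGRADABLE
    hi, lo = (c1, c2) if c1[u] >= c2[u] else (c2, c1)
    diff = hi[u] - lo[u]
    hi[u] = int(ungradable_union)
    lo[u] = int(ungradable_union) - diff
    for counts, pct in ((c1, pct_1), (c2, pct_2)):
        n = Category.NONPERFUSED
        counts[n] = total - sum(v for c, v in counts.items() if c is not n)
        for c in CATEGORY_ORDER:
            back = round_half_up(100.0 * counts[c] / total)
            if back != round_half_up(float(pct[c])):
                raise ValueError(
                    f"reconciled count {counts[c]} for {c.value} rounds to {back}%, "
                    f"contradicting the printed {pct[c]}%"
                )
        if min(counts.values()) < 0:
            raise ValueError("reconciled marginals are infeasible (negative count)")
    return c1, c2


@dataclass
class PairedCategoryData:
    """Paired per-cell categorical gradings with fixed per-grader marginals."""

    joint: pd.DataFrame  # rows = grader 1 categories, cols = grader 2
    cats_1: np.ndarray  # Category per cell, grader 1
    cats_2: np.ndarray
    total: int

    def counts(self, grader: int) -> dict[Category, int]:
        axis = 1 if grader == 1 else 0
        sums = self.joint.to_numpy().sum(axis=axis)
        return {c: int(sums[i]) for i, c in enumerate(CATEGORY_ORDER)}

    def count_difference(self, category: Category) -> int:
        """Grader 1 count minus grader 2 count for one category."""
        return self.counts(1)[category] - self.counts(2)[category]

    @property
    def n_removed_either_ungradable(self) -> int:
        j = self.joint.to_numpy()
        u = CATEGORY_ORDER.index(Category.UNGRADABLE)
        return int(j[u, :].sum() + j[:, u].sum() - j[u, u])

    @property
    def n_survivors(self) -> int:
        return self.total - self.n_removed_either_ungradable

    @property
    def fraction_same(self) -> float:
        j = self.joint.to_numpy()
        return float(np.trace(j) / self.total)

    def drop_ungradable(self) -> tuple[np.ndarray, np.ndarray]:
        keep = (self.cats_1 != Category.UNGRADABLE) & (self.cats_2 != Category.UNGRADABLE)
        return self.cats_1[keep], self.cats_2[keep]


def marginal_matched_dataset(
    total: int,
    counts_1: Mapping[Category, int],
    counts_2: Mapping[Category, int],
    seed: int = 0,
) -> PairedCategoryData:
    """Paired categorical gradings with the given exact marginal counts.

    The joint table is filled diagonal-first (maximal raw agreement subject
    to the marginals), then off-diagonal mass greedily by ascending ordinal
    distance; cell order is then shuffled deterministically by ``seed``.
    Count differences between graders depend only on the marginals, so any
    feasible joint reproduces them.
    """
    r = np.array([int(counts_1[c]) for c in CATEGORY_ORDER], dtype=np.int64)
    c = np.array([int(counts_2[c]) for c in CATEGORY_ORDER], dtype=np.int64)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("marginal counts must be non-negative")
    if r.sum() != total or c.sum() != total:
        raise ValueError(
            f"marginals are infeasible: sums {r.sum()}/{c.sum()} != total {total}"
        )
    k = len(CATEGORY_ORDER)
    joint = np.zeros((k, k), dtype=np.int64)
    rem_r, rem_c = r.copy(), c.copy()
    for i in range(k):
        m = min(rem_r[i], rem_c[i])
        joint[i, i] = m
        rem_r[i] -= m
        rem_c[i] -= m
    offdiag = sorted(
        ((i, j) for i in range(k) for j in range(k) if i != j),
        key=lambda ij: (abs(ij[0] - ij[1]), ij[0], ij[1]),
    )
    for i, j in offdiag:
        m = min(rem_r[i], rem_c[j])
        joint[i, j] += m
        rem_r[i] -= m
        rem_c[j] -= m
    assert rem_r.sum() == 0 and rem_c.sum() == 0
    pairs = np.repeat(
        np.arange(k * k), joint.reshape(-1)
    )  # flat joint index per cell
    rng = np.random.default_rng(seed)
    rng.shuffle(pairs)
    cats = np.array(CATEGORY_ORDER, dtype=object)
    labels = [cat.value for cat in CATEGORY_ORDER]
    return PairedCategoryData(
        joint=pd.DataFrame(joint, index=labels, columns=labels),
        cats_1=cats[pairs // k],
        cats_2=cats[pairs % k],
        total=int(total),
    )
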