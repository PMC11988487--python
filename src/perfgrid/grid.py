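"""Equal-area concentric grid geometry.

The grading grid is a disc partitioned into a central circular cell plus
``n_rings`` concentric annular rings. Ring ``j`` (1-based) spans radii
``[(2j-1)*r0, (2j+1)*r0)`` and is divided into ``8*j`` sectors, so every cell
— central cell and every ring sector alike — has the same analytic area
``pi * r0**2``. This is the equal-area disc partition in which the ring count
fully determines the cell count::

    cells(n) = 1 + 4 * n * (n + 1)

giving 289 cells for the default 8-ring grid and 121 for the innermost six
rings (the central region approximating the ETDRS seven standard fields).

Conventions (fixed so sector assignment is reproducible):

* grid coordinates are Cartesian with y **up**; angles increase
  counterclockwise from the positive x axis (the fovea-to-disc direction);
* every cell is the half-open product ``[r_inner, r_outer) x [theta_start,
  theta_end)``, so each interior point belongs to exactly one cell;
* ``r0 = 1`` by default — physical units attach only through the landmark
  transform and millimetre calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "OUTSIDE",
    "cell_count",
    "sectors_in_ring",
    "CellIndex",
    "CellGeometry",
    "GridSpec",
    "Region",
    "region_rings",
    "region_cells",
    "locate",
    "locate_array",
    "cell_mask",
    "label_image",
    "grid_frame",
    "save_grid_csv",
    "save_label_tiff",
]

#: Flat-id sentinel for points at or beyond the grid's outer radius.
OUTSIDE = -1

_TWO_PI = 2.0 * math.pi


def cell_count(n_rings: int) -> int:
    """Total number of cells in a grid with ``n_rings`` annular rings.

    Closed form ``1 + 4*n*(n+1)``: the central cell plus ``8*j`` sectors in
    ring ``j``, summed over rings.
    """
    n = int(n_rings)
    if n != n_rings or n < 0:
        raise ValueError(f"n_rings must be a non-negative integer, got {n_rings!r}")
    return 1 + 4 * n * (n + 1)


def sectors_in_ring(ring: int) -> int:
    """Number of sectors in ``ring`` (1 for the central cell, ``8*ring`` otherwise)."""
    if ring < 0:
        raise ValueError(f"ring must be >= 0, got {ring}")
    return 1 if ring == 0 else 8 * ring


@dataclass(frozen=True, order=True)
class CellIndex:
    """Address of one grid cell: ``(ring, sector)``.

    ``sector`` runs counterclockwise from the positive x axis and is always 0
    for the central cell. Cell indices are bijective with a flat ordinal id
    (ring-major, sector ascending) used for label rasters and CSV export.
    """

    ring: int
    sector: int = 0

    def __post_init__(self) -> None:
        if self.ring < 0:
            raise ValueError(f"ring must be >= 0, got {self.ring}")
        if not (0 <= self.sector < sectors_in_ring(self.ring)):
            raise ValueError(
                f"sector {self.sector} out of range for ring {self.ring} "
                f"(expected [0, {sectors_in_ring(self.ring)}))"
            )

    @property
    def flat(self) -> int:
        """Flat ordinal id in ``[0, cell_count(n_rings))``, ring-major."""
        return self.sector if self.ring == 0 else cell_count(self.ring - 1) + self.sector

    @staticmethod
    def from_flat(flat: int, n_rings: int) -> "CellIndex":
        if not (0 <= flat < cell_count(n_rings)):
            raise ValueError(f"flat id {flat} out of range for {n_rings} rings")
        if flat == 0:
            return CellIndex(0, 0)
        # invert flat = 1 + 4*(j-1)*j + sector with 0 <= sector < 8*j
        j = int((math.isqrt(4 * (flat - 1) + 1) + 1) // 2)
        while cell_count(j) <= flat:
            j += 1
        while cell_count(j - 1) > flat:
            j -= 1
        return CellIndex(j, flat - cell_count(j - 1))


@dataclass(frozen=True)
class CellGeometry:
    """Polar bounds of a cell: half-open ``[r_inner, r_outer) x [theta_start, theta_end)``."""

    r_inner: float
    r_outer: float
    theta_start: float
    theta_end: float

    @property
    def area(self) -> float:
        return 0.5 * (self.r_outer**2 - self.r_inner**2) * (self.theta_end - self.theta_start)

    def contains(self, r: float, theta: float) -> bool:
        theta = theta % _TWO_PI
        return (
            self.r_inner <= r < self.r_outer
            and self.theta_start <= theta < self.theta_end
        )


@dataclass(frozen=True)
class GridSpec:
    """Parameters of the equal-area concentric grading grid.

    Parameters
    ----------
    n_rings:
        Number of annular rings around the central cell (default 8).
    r0:
        Radius of the central cell in grid units (default 1; every cell has
        analytic area ``pi * r0**2``).
    fovea_disc_fraction:
        Fovea-to-disc distance expressed as a fraction of the grid diameter
        (default 0.095); used by the landmark transform to set the scale.
    """

    n_rings: int = 8
    r0: float = 1.0
    fovea_disc_fraction: float = 0.095

    def __post_init__(self) -> None:
        if int(self.n_rings) != self.n_rings or self.n_rings < 1:
            raise ValueError(f"n_rings must be an integer >= 1, got {self.n_rings!r}")
        if not (self.r0 > 0 and math.isfinite(self.r0)):
            raise ValueError(f"r0 must be positive and finite, got {self.r0!r}")
        if not (0 < self.fovea_disc_fraction < 0.5):
            raise ValueError(
                f"fovea_disc_fraction must be in (0, 0.5), got {self.fovea_disc_fraction!r}"
            )

    @property
    def total_radius(self) -> float:
        return (2 * self.n_rings + 1) * self.r0

    @property
    def diameter(self) -> float:
        return 2.0 * self.total_radius

    @property
    def n_cells(self) -> int:
        return cell_count(self.n_rings)

    def cells(self) -> Iterator[CellIndex]:
        """All cells, ring-major then sector ascending (flat-id order)."""
        for ring in range(self.n_rings + 1):
            for sector in range(sectors_in_ring(ring)):
                yield CellIndex(ring, sector)

    def geometry(self, cell: CellIndex) -> CellGeometry:
        if cell.ring > self.n_rings:
            raise ValueError(f"cell {cell} outside grid with {self.n_rings} rings")
        if cell.ring == 0:
            return CellGeometry(0.0, self.r0, 0.0, _TWO_PI)
        width = _TWO_PI / sectors_in_ring(cell.ring)
        return CellGeometry(
            (2 * cell.ring - 1) * self.r0,
            (2 * cell.ring + 1) * self.r0,
            cell.sector * width,
            (cell.sector + 1) * width,
        )


class Region(Enum):
    """Named cell regions of the grid."""

    ENTIRE = "ENTIRE"
    CENTRAL_ETDRS = "CENTRAL_ETDRS"
    PERIPHERAL = "PERIPHERAL"


#: Outermost ring (inclusive) of the central region approximating the ETDRS
#: seven standard fields; rings 0..5 hold exactly 121 cells.
CENTRAL_MAX_RING = 5


def region_rings(region: Region, grid: GridSpec) -> frozenset[int]:
    """Set of ring indices making up ``region`` on ``grid``."""
    if not isinstance(region, Region):
        try:
            region = Region(region)
        except ValueError:
            raise ValueError(f"unknown region {region!r}") from None
    all_rings = frozenset(range(grid.n_rings + 1))
    if region is Region.ENTIRE:
        return all_rings
    central = frozenset(r for r in all_rings if r <= CENTRAL_MAX_RING)
    if region is Region.CENTRAL_ETDRS:
        return central
    return all_rings - central


def region_cells(region: Region, grid: GridSpec) -> list[CellIndex]:
    """Cells of ``region`` in deterministic ring-major, sector-ascending order."""
    rings = region_rings(region, grid)
    return [c for c in grid.cells() if c.ring in rings]


def locate(x: float, y: float, grid: GridSpec) -> CellIndex | None:
    """Cell containing the grid-frame point ``(x, y)``, or ``None`` outside.

    Total function: points at radius >= ``grid.total_radius`` map to ``None``.
    """
    r = math.hypot(x, y)
    if r >= grid.total_radius:
        return None
    if r < grid.r0:
        return CellIndex(0, 0)
    ring = int((r / grid.r0 + 1.0) // 2.0)
    ring = min(ring, grid.n_rings)
    width = _TWO_PI / sectors_in_ring(ring)
    theta = math.atan2(y, x) % _TWO_PI
    sector = min(int(theta // width), sectors_in_ring(ring) - 1)
    return CellIndex(ring, sector)


def locate_array(x: np.ndarray, y: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Vectorized :func:`locate` returning flat cell ids (``OUTSIDE`` = -1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    r = np.hypot(x, y)
    ring = ((r / grid.r0 + 1.0) // 2.0).astype(np.int64)
    np.clip(ring, 0, grid.n_rings, out=ring)
    inner = r < grid.r0
    ring[inner] = 0
    n_sectors = np.where(ring == 0, 1, 8 * ring)
    theta = np.mod(np.arctan2(y, x), _TWO_PI)
    sector = np.floor(theta * n_sectors / _TWO_PI).astype(np.int64)
    np.minimum(sector, n_sectors - 1, out=sector)
    # flat id: 0 for center, cell_count(ring-1) + sector otherwise
    start = 1 + 4 * (ring - 1) * ring
    flat = np.where(ring == 0, 0, start + sector)
    flat[r >= grid.total_radius] = OUTSIDE
    return flat


# ---------------------------------------------------------------------------
# Rasterization


def _pixel_grid_coords(transform, image_shape, rows=None):
    cols = np.arange(image_shape[1], dtype=np.float64)
    if rows is None:
        rows = np.arange(image_shape[0], dtype=np.float64)
    cc, rr = np.meshgrid(cols, rows)
    pts = np.stack([cc, rr], axis=-1)
    return transform.apply(pts)


def label_image(
    grid: GridSpec, transform, image_shape: tuple[int, int], chunk_rows: int = 512
) -> np.ndarray:
    """Flat cell id of every pixel (by pixel-center), ``OUTSIDE`` off-grid.

    The grid is transformed into image coordinates (pixel centers at integer
    coordinates) rather than the image being resampled, so per-pixel cell
    membership is exact up to floating point.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"image_shape must be positive, got {image_shape!r}")
    out = np.empty((h, w), dtype=np.int64)
    for start in range(0, h, chunk_rows):
        rows = np.arange(start, min(start + chunk_rows, h), dtype=np.float64)
        g = _pixel_grid_coords(transform, (h, w), rows=rows)
        out[start : start + len(rows)] = locate_array(g[..., 0], g[..., 1], grid)
    return out


def cell_mask(
    cell: CellIndex, grid: GridSpec, transform, image_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean raster of pixels whose centers fall inside ``cell``.

    Masks of distinct cells are pairwise disjoint by the half-open boundary
    convention; their union is the pixelated grid disc.
    """
    geom = grid.geometry(cell)
    h, w = int(image_shape[0]), int(image_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"image_shape must be positive, got {image_shape!r}")
    g = _pixel_grid_coords(transform, (h, w))
    r = np.hypot(g[..., 0], g[..., 1])
    theta = np.mod(np.arctan2(g[..., 1], g[..., 0]), _TWO_PI)
    mask = (r >= geom.r_inner) & (r < geom.r_outer)
    if cell.ring > 0:
        mask &= (theta >= geom.theta_start) & (theta < geom.theta_end)
    return mask


# ---------------------------------------------------------------------------
# Export


def grid_frame(grid: GridSpec) -> pd.DataFrame:
    """Per-cell geometry table (one row per cell, flat-id order)."""
    rows = []
    for cell in grid.cells():
        geom = grid.geometry(cell)
        rows.append(
            {
                "cell_id": cell.flat,
                "ring": cell.ring,
                "sector": cell.sector,
                "r_inner": geom.r_inner,
                "r_outer": geom.r_outer,
                "theta_start": geom.theta_start,
                "theta_end": geom.theta_end,
            }
        )
    return pd.DataFrame(rows)


def save_grid_csv(grid: GridSpec, path) -> None:
    grid_frame(grid).to_csv(path, index=False)


def save_label_tiff(grid: GridSpec, transform, image_shape, path) -> None:
    """16-bit label raster: 0 = background, flat cell id + 1 otherwise."""
    import tifffile

    labels = label_image(grid, transform, image_shape)
    if grid.n_cells + 1 > np.iinfo(np.uint16).max:
        raise ValueError("grid too large for 16-bit label raster")
    tifffile.imwrite(path, (labels + 1).astype(np.uint16))
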