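"""Per-cell perfusion grades, score/category maps, and region aggregation.

Each grid cell receives one of six ordinal perfusion levels or is marked
ungradable (no visible vessel in the cell, or an image artifact such as an
eyelash shadow). The six levels carry fixed perfusion scores::

    P100 -> 1.0     fully perfused
    P76_99 -> 0.875
    P51_75 -> 0.625
    P26_50 -> 0.375
    P1_25 -> 0.125
    P0 -> 0.0       nonperfused

and collapse into three ordered categories for cross-tabulation: perfused
(exactly P100), hypoperfused (51-99% perfused) and nonperfused (0-50%
perfused). Regional perfusion is the mean score over gradable cells,
reported as percent hypoperfusion ``100 * (1 - mean score)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import IncompatibleSessionsError, UngradableScoreError
from .grid import CellIndex, GridSpec, Region, region_rings

__all__ = [
    "GradeLevel",
    "Category",
    "score_of",
    "category_of",
    "GradingSession",
    "RegionSummary",
    "region_summary",
    "PairedGrades",
    "pair_sessions",
    "CategoryTable",
    "tabulate_categories",
    "round_half_up",
]


class GradeLevel(Enum):
    """Ordinal perfusion grade of one cell (plus the UNGRADABLE marker)."""

    P0 = "P0"
    P1_25 = "P1_25"
    P26_50 = "P26_50"
    P51_75 = "P51_75"
    P76_99 = "P76_99"
    P100 = "P100"
    UNGRADABLE = "UNGRADABLE"


#: Gradable levels in ascending perfusion order (ordinal positions 0..5).
GRADABLE_LEVELS = (
    GradeLevel.P0,
    GradeLevel.P1_25,
    GradeLevel.P26_50,
    GradeLevel.P51_75,
    GradeLevel.P76_99,
    GradeLevel.P100,
)

_SCORES = {
    GradeLevel.P100: 1.0,
    GradeLevel.P76_99: 0.875,
    GradeLevel.P51_75: 0.625,
    GradeLevel.P26_50: 0.375,
    GradeLevel.P1_25: 0.125,
    GradeLevel.P0: 0.0,
}


class Category(Enum):
    """Collapsed perfusion category used for cross-tabulation."""

    PERFUSED = "perfused"
    HYPOPERFUSED = "hypoperfused"
    NONPERFUSED = "nonperfused"
    UNGRADABLE = "ungradable"


#: Ordinal category order used for weighted agreement statistics.
ORDERED_CATEGORIES = (Category.PERFUSED, Category.HYPOPERFUSED, Category.NONPERFUSED)

_CATEGORIES = {
    GradeLevel.P100: Category.PERFUSED,
    GradeLevel.P76_99: Category.HYPOPERFUSED,
    GradeLevel.P51_75: Category.HYPOPERFUSED,
    GradeLevel.P26_50: Category.NONPERFUSED,
    GradeLevel.P1_25: Category.NONPERFUSED,
    GradeLevel.P0: Category.NONPERFUSED,
    GradeLevel.UNGRADABLE: Category.UNGRADABLE,
}


def score_of(grade: GradeLevel) -> float:
    """Fixed perfusion score of a gradable level; UNGRADABLE has no score."""
    if grade is GradeLevel.UNGRADABLE:
        raise UngradableScoreError("UNGRADABLE cells carry no perfusion score")
    return _SCORES[grade]


def category_of(grade: GradeLevel) -> Category:
    """Collapsed category: perfused / hypoperfused (51-99%) / nonperfused (0-50%)."""
    return _CATEGORIES[grade]


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up to an integer (display percentages)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Sessions


@dataclass
class GradingSession:
    """One grader's per-cell grades for one image.

    ``excluded_cells`` records cells never presented to the grader (e.g. cells
    falling off the captured image field); they are disjoint from graded
    cells and contribute to no statistic except the exclusion count.
    """

    image_id: str
    grader_id: str
    grid: GridSpec
    grades: dict[CellIndex, GradeLevel]
    excluded_cells: frozenset[CellIndex] = field(default_factory=frozenset)
    created: Optional[str] = None

    def __post_init__(self) -> None:
        self.excluded_cells = frozenset(self.excluded_cells)
        valid = set(self.grid.cells())
        bad = (set(self.grades) | self.excluded_cells) - valid
        if bad:
            raise ValueError(f"cells outside the grid: {sorted(bad)[:5]}")
        overlap = set(self.grades) & self.excluded_cells
        if overlap:
            raise ValueError(f"cells both graded and excluded: {sorted(overlap)[:5]}")
        for cell, grade in self.grades.items():
            if not isinstance(grade, GradeLevel):
                raise ValueError(f"grade for {cell} is not a GradeLevel: {grade!r}")

    def to_json(self, path) -> None:
        payload = {
            "image_id": self.image_id,
            "grader_id": self.grader_id,
            "grid": {
                "n_rings": self.grid.n_rings,
                "fovea_disc_fraction": self.grid.fovea_disc_fraction,
            },
            "grades": [
                {"ring": c.ring, "sector": c.sector, "grade": g.value}
                for c, g in sorted(self.grades.items())
            ],
            "excluded": [
                {"ring": c.ring, "sector": c.sector} for c in sorted(self.excluded_cells)
            ],
        }
        if self.created is not None:
            payload["created"] = self.created
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @staticmethod
    def from_json(path) -> "GradingSession":
        with open(path) as fh:
            payload = json.load(fh)
        grid = GridSpec(
            n_rings=payload["grid"]["n_rings"],
            fovea_disc_fraction=payload["grid"].get("fovea_disc_fraction", 0.095),
        )
        grades = {
            CellIndex(e["ring"], e["sector"]): GradeLevel(e["grade"])
            for e in payload["grades"]
        }
        excluded = frozenset(
            CellIndex(e["ring"], e["sector"]) for e in payload.get("excluded", [])
        )
        return GradingSession(
            image_id=payload["image_id"],
            grader_id=payload["grader_id"],
            grid=grid,
            grades=grades,
            excluded_cells=excluded,
            created=payload.get("created"),
        )


# ---------------------------------------------------------------------------
# Region aggregation


@dataclass(frozen=True)
class RegionSummary:
    """Aggregated perfusion of one region in one session.

    ``mean_perfusion`` / ``percent_hypoperfusion`` are ``None`` (and
    ``undefined`` is set) when the region holds no gradable graded cell.
    """

    region: Region
    n_cells: int
    n_excluded: int
    n_graded: int
    n_ungradable: int
    category_counts: Mapping[Category, int]
    mean_perfusion: Optional[float]
    percent_hypoperfusion: Optional[float]

    @property
    def undefined(self) -> bool:
        return self.mean_perfusion is None


def region_summary(session: GradingSession, region: Region) -> RegionSummary:
    """Average perfusion score over a region's gradable cells.

    Ungradable cells appear in the category counts but are excluded from the
    mean; excluded (never-presented) cells contribute only to ``n_excluded``.
    """
    rings = region_rings(region, session.grid)
    cells = [c for c in session.grid.cells() if c.ring in rings]
    cellset = set(cells)
    counts = {c: 0 for c in Category}
    scores = []
    n_excluded = len(session.excluded_cells & cellset)
    n_graded = 0
    for cell in cells:
        grade = session.grades.get(cell)
        if grade is None:
            continue
        n_graded += 1
        counts[category_of(grade)] += 1
        if grade is not GradeLevel.UNGRADABLE:
            scores.append(score_of(grade))
    if scores:
        mean = float(np.mean(scores))
        pct_hypo = 100.0 * (1.0 - mean)
    else:
        mean = pct_hypo = None
    return RegionSummary(
        region=region,
        n_cells=len(cells),
        n_excluded=n_excluded,
        n_graded=n_graded,
        n_ungradable=counts[Category.UNGRADABLE],
        category_counts=counts,
        mean_perfusion=mean,
        percent_hypoperfusion=pct_hypo,
    )


# ---------------------------------------------------------------------------
# Pairing two graders


@dataclass
class PairedGrades:
    """Cell-by-cell grades of two graders on the same image.

    ``table`` has one row per cell graded by BOTH graders, columns
    ``ring, sector, grade_1, grade_2`` (GradeLevel values).
    ``n_removed_ungradable`` counts rows dropped because either grader marked
    the cell ungradable (0 when no filtering was requested).
    """

    image_id: str
    grader_1: str
    grader_2: str
    grid: GridSpec
    table: pd.DataFrame
    n_common: int
    n_removed_ungradable: int = 0


def pair_sessions(
    a: GradingSession,
    b: GradingSession,
    drop_if_either_ungradable: bool = False,
) -> PairedGrades:
    """Align two graders' sessions cell-by-cell.

    With ``drop_if_either_ungradable`` the rows where either grade is
    UNGRADABLE are removed (the paper-style "disregarding ungradable"
    analysis) and the removed count is recorded.
    """
    if a.grader_id == b.grader_id:
        raise IncompatibleSessionsError("cannot pair a session with itself (same grader)")
    if a.image_id != b.image_id:
        raise IncompatibleSessionsError(
            f"sessions grade different images: {a.image_id!r} vs {b.image_id!r}"
        )
    if a.grid != b.grid:
        raise IncompatibleSessionsError("sessions use different grids")
    common = sorted(set(a.grades) & set(b.grades))
    rows = [
        {"ring": c.ring, "sector": c.sector, "grade_1": a.grades[c], "grade_2": b.grades[c]}
        for c in common
    ]
    table = pd.DataFrame(rows, columns=["ring", "sector", "grade_1", "grade_2"])
    n_common = len(table)
    removed = 0
    if drop_if_either_ungradable and n_common:
        keep = ~(
            (table["grade_1"] == GradeLevel.UNGRADABLE)
            | (table["grade_2"] == GradeLevel.UNGRADABLE)
        )
        removed = int((~keep).sum())
        table = table[keep].reset_index(drop=True)
    return PairedGrades(
        image_id=a.image_id,
        grader_1=a.grader_id,
        grader_2=b.grader_id,
        grid=a.grid,
        table=table,
        n_common=n_common,
        n_removed_ungradable=removed,
    )


# ---------------------------------------------------------------------------
# Category tabulation


@dataclass
class CategoryTable:
    """Per-grader category counts/percentages over a region (report layout).

    ``counts`` holds exact integer counts (rows = categories, columns =
    grader ids); ``percent`` the exact fractions in percent;
    ``display_percent`` the half-up integer rounding used for printed
    tables. ``differences`` is ``grader_1 count - grader_2 count`` per
    category (positive when grader 1 assigned the category more often).
    """

    region: Region
    cells_graded: int
    counts: pd.DataFrame
    percent: pd.DataFrame
    display_percent: pd.DataFrame
    differences: pd.Series


def tabulate_categories(pairs: Iterable[PairedGrades], region: Region) -> CategoryTable:
    """Pool paired cells over images and tabulate per-grader category shares.

    Reproduces the printed comparison layout: cells graded plus the percent
    perfused / hypoperfused / nonperfused (/ ungradable, when present) per
    grader, with the per-category count differences between graders.
    Percentages are rounded half-up for display; exact fractions are kept.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("tabulate_categories requires at least one paired image")
    g1 = pairs[0].grader_1
    g2 = pairs[0].grader_2
    rings = region_rings(region, pairs[0].grid)
    counts = {g1: {c: 0 for c in Category}, g2: {c: 0 for c in Category}}
    total = 0
    for p in pairs:
        if (p.grader_1, p.grader_2) != (g1, g2):
            raise IncompatibleSessionsError("paired tables mix different grader pairs")
        sub = p.table[p.table["ring"].isin(rings)]
        total += len(sub)
        for grade in sub["grade_1"]:
            counts[g1][category_of(grade)] += 1
        for grade in sub["grade_2"]:
            counts[g2][category_of(grade)] += 1
    cats = list(Category)
    if counts[g1][Category.UNGRADABLE] == 0 and counts[g2][Category.UNGRADABLE] == 0:
        cats = [c for c in cats if c is not Category.UNGRADABLE]
    index = [c.value for c in cats]
    count_df = pd.DataFrame(
        {g: [counts[g][c] for c in cats] for g in (g1, g2)}, index=index, dtype=int
    )
    pct = 100.0 * count_df / total if total else count_df * np.nan
    display = pct.map(round_half_up) if total else pct
    diffs = count_df[g1] - count_df[g2]
    return CategoryTable(
        region=region,
        cells_graded=total,
        counts=count_df,
        percent=pct,
        display_percent=display,
        differences=diffs,
    )
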