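"""Grade maps, region aggregation, session pairing and category tabulation."""

import numpy as np
import pytest

from perfgrid import (
    Category,
    GradeLevel,
    GradingSession,
    GridSpec,
    Region,
    category_of,
    pair_sessions,
    region_summary,
    score_of,
    tabulate_categories,
)
from perfgrid.errors import IncompatibleSessionsError, UngradableScoreError
from perfgrid.grading import GRADABLE_LEVELS, round_half_up
from perfgrid.grid import CellIndex


class TestScoreAndCategoryMaps:
    @pytest.mark.parametrize(
        "grade,score",
        [
            (GradeLevel.P100, 1.0),
            (GradeLevel.P76_99, 0.875),
            (GradeLevel.P51_75, 0.625),
            (GradeLevel.P26_50, 0.375),
            (GradeLevel.P1_25, 0.125),
            (GradeLevel.P0, 0.0),
        ],
    )
    def test_score_map(self, grade, score):
        assert score_of(grade) == score

    def test_ungradable_has_no_score(self):
        with pytest.raises(UngradableScoreError):
            score_of(GradeLevel.UNGRADABLE)

    @pytest.mark.parametrize(
        "grade,category",
        [
            (GradeLevel.P100, Category.PERFUSED),
            (GradeLevel.P76_99, Category.HYPOPERFUSED),
            (GradeLevel.P51_75, Category.HYPOPERFUSED),
            (GradeLevel.P26_50, Category.NONPERFUSED),
            (GradeLevel.P1_25, Category.NONPERFUSED),
            (GradeLevel.P0, Category.NONPERFUSED),
            (GradeLevel.UNGRADABLE, Category.UNGRADABLE),
        ],
    )
    def test_category_map(self, grade, category):
        assert category_of(grade) is category

    def test_nonperfused_iff_score_at_most_0375(self):
        for g in GRADABLE_LEVELS:
            assert (category_of(g) is Category.NONPERFUSED) == (score_of(g) <= 0.375)


def _session(grid, grades, grader="g1", image="img", excluded=frozenset()):
    return GradingSession(image, grader, grid, grades, excluded_cells=excluded)


class TestRegionSummary:
    def test_all_perfused_gives_zero_hypoperfusion(self, default_grid):
        grades = {c: GradeLevel.P100 for c in default_grid.cells()}
        rs = region_summary(_session(default_grid, grades), Region.ENTIRE)
        assert rs.percent_hypoperfusion == 0.0

    def test_mixed_grades_example(self):
        grid = GridSpec(n_rings=1)
        cells = list(grid.cells())
        grades = {
            cells[0]: GradeLevel.P100,
            cells[1]: GradeLevel.P76_99,
            cells[2]: GradeLevel.P0,
        }
        rs = region_summary(_session(grid, grades), Region.ENTIRE)
        assert rs.mean_perfusion == pytest.approx((1 + 0.875 + 0) / 3)
        assert rs.percent_hypoperfusion == pytest.approx(37.5)

    def test_all_ungradable_is_flagged_undefined(self, default_grid):
        grades = {c: GradeLevel.UNGRADABLE for c in default_grid.cells()}
        rs = region_summary(_session(default_grid, grades), Region.ENTIRE)
        assert rs.undefined
        assert rs.percent_hypoperfusion is None
        assert rs.n_ungradable == 289

    def test_aggregation_linearity(self, default_grid, rng):
        """ENTIRE mean equals the graded-count-weighted blend of the regions."""
        levels = list(GRADABLE_LEVELS)
        grades = {
            c: levels[rng.integers(0, 6)] for c in default_grid.cells()
        }
        s = _session(default_grid, grades)
        entire = region_summary(s, Region.ENTIRE)
        central = region_summary(s, Region.CENTRAL_ETDRS)
        periph = region_summary(s, Region.PERIPHERAL)
        blended = (
            central.mean_perfusion * central.n_graded
            + periph.mean_perfusion * periph.n_graded
        ) / (central.n_graded + periph.n_graded)
        assert entire.mean_perfusion == pytest.approx(blended, rel=1e-12)

    def test_excluded_cells_only_counted(self, default_grid):
        cells = list(default_grid.cells())
        grades = {c: GradeLevel.P100 for c in cells[: 100]}
        excluded = frozenset(cells[200:250])
        rs = region_summary(
            _session(default_grid, grades, excluded=excluded), Region.ENTIRE
        )
        assert rs.n_excluded == 50
        assert rs.n_graded == 100
        assert rs.percent_hypoperfusion == 0.0

    def test_overlapping_graded_and_excluded_rejected(self, default_grid):
        c = CellIndex(0, 0)
        with pytest.raises(ValueError):
            _session(default_grid, {c: GradeLevel.P100}, excluded=frozenset({c}))


class TestPairSessions:
    def test_self_pairing_forbidden(self, default_grid):
        grades = {CellIndex(0, 0): GradeLevel.P100}
        a = _session(default_grid, grades, grader="g1")
        with pytest.raises(IncompatibleSessionsError):
            pair_sessions(a, a)

    def test_mismatched_grids_rejected(self):
        a = _session(GridSpec(), {CellIndex(0, 0): GradeLevel.P100}, grader="g1")
        b = _session(GridSpec(n_rings=5), {CellIndex(0, 0): GradeLevel.P100}, grader="g2")
        with pytest.raises(IncompatibleSessionsError):
            pair_sessions(a, b)

    def test_no_ungradable_keeps_all_common_cells(self, default_grid):
        cells = list(default_grid.cells())
        a = _session(default_grid, {c: GradeLevel.P100 for c in cells[:50]}, "g1")
        b = _session(default_grid, {c: GradeLevel.P0 for c in cells[20:80]}, "g2")
        p = pair_sessions(a, b, drop_if_either_ungradable=True)
        assert p.n_common == 30
        assert p.n_removed_ungradable == 0

    def test_union_removal_count(self, default_grid, rng):
        """Survivors = common - |union of either grader's ungradable cells|."""
        cells = list(default_grid.cells())
        ga = {c: GradeLevel.P100 for c in cells}
        gb = {c: GradeLevel.P100 for c in cells}
        ung_a = set(rng.choice(len(cells), size=10, replace=False).tolist())
        ung_b = set(rng.choice(len(cells), size=4, replace=False).tolist())
        for i in ung_a:
            ga[cells[i]] = GradeLevel.UNGRADABLE
        for i in ung_b:
            gb[cells[i]] = GradeLevel.UNGRADABLE
        p = pair_sessions(
            _session(default_grid, ga, "g1"),
            _session(default_grid, gb, "g2"),
            drop_if_either_ungradable=True,
        )
        union = len(ung_a | ung_b)
        assert p.n_removed_ungradable == union
        assert len(p.table) == 289 - union
        # monotonicity: dropping on the union removes at least each single set
        assert len(p.table) <= 289 - len(ung_a)
        assert len(p.table) <= 289 - len(ung_b)


class TestTabulateCategories:
    def test_all_perfused_single_image(self, default_grid):
        cells = list(default_grid.cells())
        a = _session(default_grid, {c: GradeLevel.P100 for c in cells}, "g1")
        b = _session(default_grid, {c: GradeLevel.P100 for c in cells}, "g2")
        tab = tabulate_categories([pair_sessions(a, b)], Region.ENTIRE)
        assert tab.cells_graded == 289
        assert tab.display_percent.loc["perfused", "g1"] == 100
        assert (tab.differences == 0).all()

    def test_counts_reconstructable_from_exact_fractions(self, default_grid, rng):
        levels = list(GradeLevel)
        ga = {c: levels[rng.integers(0, 7)] for c in default_grid.cells()}
        gb = {c: levels[rng.integers(0, 7)] for c in default_grid.cells()}
        tab = tabulate_categories(
            [pair_sessions(_session(default_grid, ga, "g1"),
                           _session(default_grid, gb, "g2"))],
            Region.ENTIRE,
        )
        rebuilt = (tab.percent * tab.cells_graded / 100.0).round().astype(int)
        assert (rebuilt == tab.counts).all().all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate_categories([], Region.ENTIRE)


class TestSessionJson:
    def test_round_trip(self, default_grid, tmp_path, rng):
        levels = list(GradeLevel)
        cells = list(default_grid.cells())
        grades = {c: levels[rng.integers(0, 7)] for c in cells[:250]}
        s = _session(default_grid, grades, excluded=frozenset(cells[250:260]))
        path = tmp_path / "session.json"
        s.to_json(path)
        back = GradingSession.from_json(path)
        assert back.grades == s.grades
        assert back.excluded_cells == s.excluded_cells
        assert back.grid == s.grid
        assert back.image_id == s.image_id


def test_round_half_up():
    assert round_half_up(2.5) == 3
    assert round_half_up(2.49) == 2
    assert round_half_up(0.0) == 0
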