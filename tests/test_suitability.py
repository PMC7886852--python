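"""Weighted suitability overlay, classification, area and grid I/O."""

import numpy as np
import pytest

from corecc import (
    FactorLayer,
    SuitabilityClass,
    ValidationError,
    classify_suitability,
    read_ascii_grid,
    score_cells,
    suitable_area,
    write_ascii_grid,
)
from corecc.suitability import NODATA_DEFAULT, class_areas


def overlay_oracle(grids, weights, nodata=NODATA_DEFAULT):
    """Naive per-cell loop re-implementation of the weighted overlay."""
    nrows, ncols = grids[0].shape
    out = np.empty((nrows, ncols))
    for r in range(nrows):
        for c in range(ncols):
            if grids[0][r, c] == nodata:
                out[r, c] = nodata
            elif any(g[r, c] == 0 for g in grids):
                out[r, c] = 0.0
            else:
                out[r, c] = sum(w * g[r, c] for w, g in zip(weights, grids))
    return out


def _layers(grids, weights, cellsize=1.0):
    return [
        FactorLayer(name=f"f{i}", weight=w, grid=g, cellsize=cellsize)
        for i, (g, w) in enumerate(zip(grids, weights))
    ]


class TestScoreCells:
    def test_weighted_mean(self):
        grid = score_cells(_layers([np.full((2, 2), 4.0), np.full((2, 2), 2.0)], [0.5, 0.5]))
        assert np.allclose(grid.scores, 3.0)

    def test_forbidden_veto(self):
        """A zero grade in any layer forces the cell score to zero."""
        a = np.array([[5.0, 0.0], [3.0, 5.0]])
        b = np.array([[5.0, 5.0], [0.0, 5.0]])
        grid = score_cells(_layers([a, b], [0.4, 0.6]))
        assert grid.scores[0, 1] == 0.0
        assert grid.scores[1, 0] == 0.0
        assert grid.scores[0, 0] == pytest.approx(5.0)

    def test_matches_per_cell_oracle_on_random_grids(self, rng):
        for _ in range(20):
            grids = [
                rng.choice([0.0, 1.0, 3.0, 5.0], size=(8, 8), p=[0.1, 0.3, 0.3, 0.3])
                for _ in range(4)
            ]
            w = rng.uniform(0.1, 1.0, size=4)
            w = (w / w.sum()).tolist()
            got = score_cells(_layers(grids, w)).scores
            np.testing.assert_allclose(got, overlay_oracle(grids, w), rtol=1e-12)

    def test_nodata_propagates(self):
        a = np.array([[NODATA_DEFAULT, 3.0]])
        b = np.array([[NODATA_DEFAULT, 5.0]])
        grid = score_cells(_layers([a, b], [0.5, 0.5]))
        assert grid.scores[0, 0] == NODATA_DEFAULT
        assert grid.scores[0, 1] == pytest.approx(4.0)

    def test_score_bounded_by_grades(self, rng):
        """With all grades > 0 the score lies within [min, max] grade."""
        grids = [rng.choice([1.0, 3.0, 5.0], size=(6, 6)) for _ in range(3)]
        w = [0.2, 0.3, 0.5]
        scores = score_cells(_layers(grids, w)).scores
        lo = np.minimum.reduce(grids)
        hi = np.maximum.reduce(grids)
        assert np.all(scores >= lo - 1e-12) and np.all(scores <= hi + 1e-12)

    def test_monotone_in_grades(self, rng):
        grids = [rng.choice([1.0, 3.0], size=(4, 4)) for _ in range(2)]
        w = [0.5, 0.5]
        base = score_cells(_layers(grids, w)).scores
        grids2 = [grids[0] + 1.0, grids[1]]
        assert np.all(score_cells(_layers(grids2, w)).scores >= base)

    def test_weight_sum_violation(self):
        with pytest.raises(ValidationError, match="weights"):
            score_cells(_layers([np.ones((2, 2)), np.ones((2, 2))], [0.5, 0.4]))

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError, match="shape"):
            score_cells(_layers([np.ones((2, 2)), np.ones((3, 2))], [0.5, 0.5]))

    def test_negative_grades_rejected(self):
        with pytest.raises(ValidationError):
            FactorLayer(name="bad", weight=0.5, grid=np.array([[-1.0]]))


class TestClassifyAndArea:
    def test_four_level_classification(self):
        layer = FactorLayer(
            name="only", weight=1.0, grid=np.array([[0.0, 1.0], [3.0, 4.5]])
        )
        grid = classify_suitability(score_cells([layer]), (2.0, 4.0))
        assert grid.classes[0, 0] == SuitabilityClass.FORBIDDEN
        assert grid.classes[0, 1] == SuitabilityClass.LIMITED
        assert grid.classes[1, 0] == SuitabilityClass.LESS_SUITABLE
        assert grid.classes[1, 1] == SuitabilityClass.SUITABLE

    def test_suitable_area_counts_cells(self):
        layer = FactorLayer(
            name="only", weight=1.0, grid=np.array([[0.0, 1.0], [3.0, 4.5]]),
            cellsize=10.0,
        )
        grid = classify_suitability(score_cells([layer]), (2.0, 4.0))
        assert suitable_area(grid) == pytest.approx(200.0)  # 2 cells x 100 m^2
        areas = class_areas(grid)
        assert areas["forbidden"] == 100.0 and areas["limited"] == 100.0

    def test_all_scores_below_t1_gives_zero_area(self):
        layer = FactorLayer(name="only", weight=1.0, grid=np.full((3, 3), 1.0))
        grid = classify_suitability(score_cells([layer]), (2.0, 4.0))
        assert suitable_area(grid) == 0.0

    def test_area_matches_counting_oracle(self, rng):
        layer = FactorLayer(
            name="only", weight=1.0,
            grid=rng.choice([0.0, 1.0, 3.0, 5.0], size=(8, 8)), cellsize=5.0,
        )
        grid = classify_suitability(score_cells([layer]), (2.0, 4.0))
        want = sum(
            25.0
            for v in layer.grid.ravel()
            if v >= 2.0  # scores equal grades for a single unit-weight layer
        )
        assert suitable_area(grid) == pytest.approx(want)

    def test_area_monotone_as_thresholds_decrease(self, rng):
        layer = FactorLayer(
            name="only", weight=1.0, grid=rng.uniform(0.1, 5.0, size=(8, 8))
        )
        scored = score_cells([layer])
        a_tight = suitable_area(classify_suitability(scored, (3.0, 4.0)))
        a_loose = suitable_area(classify_suitability(scored, (1.0, 2.0)))
        assert a_loose >= a_tight

    def test_errors(self):
        layer = FactorLayer(name="only", weight=1.0, grid=np.ones((2, 2)))
        scored = score_cells([layer])
        with pytest.raises(ValidationError):
            classify_suitability(scored, (4.0, 2.0))
        fresh = score_cells([layer])
        with pytest.raises(ValidationError, match="classified"):
            suitable_area(fresh)


class TestAsciiGridIO:
    def test_round_trip_bit_exact(self, rng, tmp_path):
        grid = rng.uniform(0, 5, size=(6, 4))
        grid[0, 0] = NODATA_DEFAULT
        path = tmp_path / "layer.asc"
        write_ascii_grid(path, grid, cellsize=12.5, xllcorner=1.25, yllcorner=-3.5)
        back, header = read_ascii_grid(path)
        assert np.array_equal(back, grid)  # bit-exact
        assert header["cellsize"] == 12.5
        assert header["xllcorner"] == 1.25
        assert header["nodata_value"] == NODATA_DEFAULT

    def test_header_shape_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\nnrows 2\ncellsize 1.0\n1 2 3\n")
        with pytest.raises(ValidationError, match="shape"):
            read_ascii_grid(p)
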