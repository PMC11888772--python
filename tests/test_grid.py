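"""The 16-square grid construction and Battleship weighted-sum scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bstmap import (
    ValidationError,
    bst_from_grid,
    bst_from_map,
    build_grid,
    classify,
    compute_dmc,
    compute_weighted_sums,
    find_anatomical_center,
    square_mean_distances,
)
from bstmap.grid import CENTER_OFFSETS, GRADIENT_GAIN, _grid_square_stats

from conftest import make_projected_map, tws_oracle


def square_index(row, col):
    return row * 4 + col


class TestAnatomicalCenter:
    def test_symmetric_extents(self):
        pm = make_projected_map([-10, 10, 0], [15, -15, 0])
        assert find_anatomical_center(pm) == (0.0, 0.0)

    def test_midpoint_of_extents(self):
        pm = make_projected_map([0, 30, 10], [10, 20, 12])
        assert find_anatomical_center(pm) == (15.0, 15.0)

    def test_osteophyte_outlier_excluded(self):
        pm = make_projected_map(
            [-10, 10, 80], [15, -15, 0],
            flags=np.array(["valid", "valid", "excluded"], dtype=object),
        )
        assert find_anatomical_center(pm) == (0.0, 0.0)

    def test_no_samples_rejected(self):
        pm = make_projected_map([1.0], [1.0], flags=np.array(["excluded"], dtype=object))
        with pytest.raises(ValidationError):
            find_anatomical_center(pm)


class TestBuildGrid:
    def test_corner_square_center_norm(self):
        pm = make_projected_map([-10, 10], [-15, 15])
        grid = build_grid(pm)
        al = next(s for s in grid.squares if s.row == 3 and s.col == 3)
        assert al.center_norm == (0.375, 0.375)
        assert al.quadrant == "AL"

    def test_four_squares_per_quadrant(self):
        pm = make_projected_map([-10, 10], [-15, 15])
        grid = build_grid(pm)
        quadrants = [s.quadrant for s in grid.squares]
        assert sorted(set(quadrants)) == ["AL", "AM", "PL", "PM"]
        for q in "AL", "AM", "PL", "PM":
            assert quadrants.count(q) == 4

    def test_off_centre_axes_keep_equal_squares(self):
        """Squares remain equal subdivisions of the rectangle; quadrant
        membership follows each square's own centre relative to the axes."""
        pm = make_projected_map([0, 8], [0, 8])
        grid = build_grid(pm, center=(1.0, 1.0))  # axes near the PM corner
        widths = {round(s.x_bounds[1] - s.x_bounds[0], 12) for s in grid.squares}
        assert widths == {2.0}
        # every square whose centre is lateral/anterior of (1,1) is A*/ *L
        for s in grid.squares:
            cx_mm = (s.x_bounds[0] + s.x_bounds[1]) / 2
            cy_mm = (s.y_bounds[0] + s.y_bounds[1]) / 2
            assert s.quadrant == ("A" if cy_mm > 1 else "P") + ("L" if cx_mm > 1 else "M")
        # with axes at (1,1) only the single posterior-medial square is PM
        assert sum(s.quadrant == "PM" for s in grid.squares) == 1

    def test_zero_area_rejected(self):
        pm = make_projected_map([1, 1, 1], [0, 1, 2])
        with pytest.raises(ValidationError):
            build_grid(pm)

    def test_centre_outside_extents_rejected(self):
        pm = make_projected_map([0, 8], [0, 8])
        with pytest.raises(ValidationError):
            build_grid(pm, center=(20.0, 4.0))


class TestSquareMeans:
    def grid_on_unit16(self):
        pm = make_projected_map([0, 4], [0, 4])
        return pm, build_grid(pm)

    def test_constant_field(self):
        xs, ys = np.meshgrid(np.linspace(0, 4, 9), np.linspace(0, 4, 9))
        pm = make_projected_map(xs.ravel(), ys.ravel(), np.full(81, 0.4))
        stats = square_mean_distances(pm, build_grid(pm))
        assert all(s.mean_distance == pytest.approx(0.4) for s in stats)
        assert all(not s.flag_empty for s in stats)

    def test_boundary_sample_goes_positive_side(self):
        # interior boundary at x = 2: the sample belongs to column 2, not 1
        pm = make_projected_map([0, 4, 2.0], [0, 4, 0.5], [1.0, 1.0, 0.0])
        stats = square_mean_distances(pm, build_grid(pm))
        target = next(s for s in stats if s.row == 0 and s.col == 2)
        assert target.n_samples == 1
        assert target.mean_distance == pytest.approx(0.0)

    def test_fully_cystic_square(self):
        pm = make_projected_map(
            [4, 0, 0.5, 0.6], [0, 4, 0.5, 0.6],
            [1.0, 1.0, np.nan, np.nan],
            flags=np.array(["valid", "valid", "cyst", "cyst"], dtype=object),
        )
        stats = square_mean_distances(pm, build_grid(pm))
        pm00 = next(s for s in stats if s.row == 0 and s.col == 0)
        assert pm00.cyst_fraction == pytest.approx(1.0)
        assert pm00.mean_distance == pytest.approx(0.0)
        assert compute_dmc(pm00.mean_distance, pm00.cyst_fraction) == pytest.approx(1.0)

    def test_empty_squares_flagged_not_fatal(self):
        pm = make_projected_map([0, 4], [0, 4], [0.2, 0.2])
        stats = square_mean_distances(pm, build_grid(pm))
        assert sum(s.flag_empty for s in stats) == 14


class TestDmc:
    @pytest.mark.parametrize(
        "mean_distance, expected",
        [(0.3, 0.7), (0.0, 1.0), (2.5, -1.5), (1.0, 0.0)],
    )
    def test_formula(self, mean_distance, expected):
        assert compute_dmc(mean_distance) == pytest.approx(expected)

    def test_empty_square_has_no_dmc(self):
        assert np.isnan(compute_dmc(np.nan, flag_empty=True))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            compute_dmc(-0.1)


class TestWeightedSums:
    def test_uniform_dmc_centres_at_origin(self):
        stats = _grid_square_stats(np.full(16, 0.37), np.zeros(16, dtype=bool))
        for s in stats:
            s.dmc = compute_dmc(s.mean_distance)
        tws = compute_weighted_sums(stats)
        assert tws == pytest.approx((0.0, 0.0), abs=1e-15)

    def test_single_al_corner_square(self):
        d = np.ones(16)
        d[square_index(3, 3)] = 0.0  # DMC 1 in the AL corner, 0 elsewhere
        res = bst_from_grid(d)
        assert res.tws_x == pytest.approx(0.0234375, abs=1e-12)
        assert res.tws_y == pytest.approx(0.0234375, abs=1e-12)

    def test_linear_gradient_closed_form(self):
        g = 0.8
        d = 0.5 + g * np.tile(CENTER_OFFSETS, 4)
        res = bst_from_grid(d)
        assert res.tws_x == pytest.approx(GRADIENT_GAIN * g, abs=1e-12)
        assert res.tws_y == pytest.approx(0.0, abs=1e-12)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValidationError):
            compute_weighted_sums([])


class TestClassify:
    @pytest.mark.parametrize(
        "tws, expected",
        [
            ((-0.10, 0.05), ("varus", "anterior")),
            ((0.02, -0.03), ("valgus", "posterior")),
            ((0.0, 0.0), ("neutral", "neutral")),
        ],
    )
    def test_sign_rules(self, tws, expected):
        assert classify(*tws) == expected

    def test_rounding_gives_neutral_band(self):
        # |TWS| below 5e-4 rounds to 0 at the default 3 decimals
        assert classify(4e-4, -4e-4) == ("neutral", "neutral")
        assert classify(4e-4, -4e-4, decimals=None) == ("valgus", "posterior")

    def test_zero_tol(self):
        assert classify(-0.01, 0.01, zero_tol=0.02) == ("neutral", "neutral")


class TestBstFromGrid:
    def test_constant_field_is_neutral(self):
        res = bst_from_grid(np.full(16, 0.5))
        assert res.tws_x == pytest.approx(0.0, abs=1e-15)
        assert (res.coronal_class, res.sagittal_class) == ("neutral", "neutral")

    def test_medial_contact_is_varus(self):
        d = np.tile([0.2, 0.2, 0.8, 0.8], 4)  # medial columns closer
        res = bst_from_grid(d, side="right")
        assert res.tws_x < 0
        assert res.coronal_class == "varus"

    def test_left_foot_mirror_consistency(self):
        """A left foot's image-frame table (columns lateral→medial) mirrors
        back to the same anatomical pattern and the same result."""
        d_right = np.tile([0.2, 0.2, 0.8, 0.8], 4)
        d_left_image = d_right.reshape(4, 4)[:, ::-1].reshape(16)
        right = bst_from_grid(d_right, side="right")
        left = bst_from_grid(d_left_image, side="left")
        assert left.tws_x == pytest.approx(right.tws_x, abs=1e-12)
        assert left.tws_y == pytest.approx(right.tws_y, abs=1e-12)
        assert left.coronal_class == right.coronal_class == "varus"

    def test_validation(self):
        with pytest.raises(ValidationError):
            bst_from_grid(np.ones(15))
        with pytest.raises(ValidationError):
            bst_from_grid(np.full(16, -0.1))

    def test_empty_squares_contribute_zero_divisor_sixteen(self):
        d = np.full(16, 1.0)  # DMC 0 everywhere
        d[square_index(0, 0)] = np.nan  # empty square
        d[square_index(3, 3)] = 0.0  # DMC 1
        res = bst_from_grid(d)
        assert res.tws_x == pytest.approx(0.375 / 16, abs=1e-12)


# ---------------------------------------------------------------------------
# properties


finite_distance = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)


class TestProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(finite_distance, min_size=16, max_size=16))
    def test_oracle_resummation(self, distances):
        res = bst_from_grid(np.array(distances))
        ox, oy = tws_oracle(distances)
        assert res.tws_x == pytest.approx(ox, abs=1e-12)
        assert res.tws_y == pytest.approx(oy, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(finite_distance, min_size=16, max_size=16))
    def test_mirror_equivariance(self, distances):
        d = np.array(distances)
        mirrored = d.reshape(4, 4)[:, ::-1].reshape(16)
        res = bst_from_grid(d, decimals=None)
        mir = bst_from_grid(mirrored, decimals=None)
        assert mir.tws_x == pytest.approx(-res.tws_x, abs=1e-12)
        assert mir.tws_y == pytest.approx(res.tws_y, abs=1e-12)
        swap = {"varus": "valgus", "valgus": "varus", "neutral": "neutral"}
        assert mir.coronal_class == swap[res.coronal_class]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(finite_distance, min_size=16, max_size=16))
    def test_tws_bound(self, distances):
        res = bst_from_grid(np.array(distances))
        max_dmc = max(abs(1 - d) for d in distances)
        assert abs(res.tws_x) <= 0.375 * max_dmc + 1e-12
        assert abs(res.tws_y) <= 0.375 * max_dmc + 1e-12

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(finite_distance, min_size=8, max_size=8))
    def test_even_field_null(self, half):
        """A field even in x has TWSx = 0; build columns mirrored in pairs."""
        rows = np.array(half).reshape(4, 2)
        full = np.column_stack([rows, rows[:, ::-1]])
        # columns are c0, c1, c1, c0 -> even about the midline
        res = bst_from_grid(full.reshape(16))
        assert abs(res.tws_x) < 1e-12

    def test_map_and_grid_paths_agree(self, rng):
        """Scoring a sampled map agrees with the mesh-free entry point when
        samples are square-centred."""
        d16 = rng.uniform(0.1, 0.9, 16)
        centers_x = np.tile(CENTER_OFFSETS, 4) * 8  # rectangle [-4, 4]^2
        centers_y = np.repeat(CENTER_OFFSETS, 4) * 8
        # corner pins fix the bounding rectangle; they repeat the corner
        # squares' values so every square mean stays d16
        pm = make_projected_map(
            np.concatenate([centers_x, [-4, 4]]),
            np.concatenate([centers_y, [-4, 4]]),
            np.concatenate([d16, [d16[0], d16[15]]]),
        )
        res_map = bst_from_map(pm)
        res_grid = bst_from_grid(d16)
        assert res_map.tws_x == pytest.approx(res_grid.tws_x, abs=1e-12)
        assert res_map.tws_y == pytest.approx(res_grid.tws_y, abs=1e-12)
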