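"""Aperture geometry: shifting, rasterization, dilation, leaf fitting."""

import logging

import numpy as np
import pytest
import shapely

from mlcmargins import (AperturePolygon, BankGeometry, MarginSpec, RasterMask,
                        build_dilation_kernel, circle_aperture, dilate,
                        fit_leaves, mask_to_polygon, rasterize, set_jaws,
                        shift_aperture)
from mlcmargins.geometry import (ApertureVanishedError, GeometryError,
                                 _dilate_1d, polygon_row_extents)

from conftest import random_convex_polygon


class TestAperturePolygon:
    def test_orientation_normalized_to_ccw(self):
        cw = AperturePolygon(np.array([[-5.0, -5.0], [-5.0, 5.0],
                                       [5.0, 5.0], [5.0, -5.0]]))
        x, y = cw.vertices[:, 0], cw.vertices[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0

    def test_rejects_self_intersection(self):
        bowtie = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        with pytest.raises(GeometryError):
            AperturePolygon(bowtie)

    @pytest.mark.parametrize("bad", [
        np.array([[0.0, 0.0], [1.0, 0.0]]),
        np.array([[0.0, 0.0], [1.0, np.nan], [1.0, 1.0]]),
    ])
    def test_rejects_invalid_vertices(self, bad):
        with pytest.raises(GeometryError):
            AperturePolygon(bad)


class TestShiftAperture:
    def test_zero_shift_is_identity(self, square10):
        out = shift_aperture(square10, (0.0, 0.0))
        np.testing.assert_array_equal(out.vertices, square10.vertices)

    def test_pure_translation(self):
        sq = AperturePolygon(np.array([[25.0, -25.0], [25.0, 25.0],
                                       [-25.0, 25.0], [-25.0, -25.0]]))
        out = shift_aperture(sq, (3.0, -2.0))
        expected = {(28.0, -27.0), (28.0, 23.0), (-22.0, 23.0), (-22.0, -27.0)}
        assert {tuple(v) for v in out.vertices} == expected

    def test_area_preserved(self, rng):
        poly = random_convex_polygon(rng)
        shifted = shift_aperture(poly, (17.3, -41.9))
        assert shifted.area == pytest.approx(poly.area, rel=1e-12)

    def test_rejects_non_finite_displacement(self, square10):
        with pytest.raises(GeometryError):
            shift_aperture(square10, (np.inf, 0.0))


class TestDilationKernel:
    def test_worked_example_4mm_2mm(self):
        n_minus, n_center, n_plus = build_dilation_kernel((4.0, 2.0), 0.25)
        assert (n_minus, n_center, n_plus) == (16, 1, 8)
        assert n_minus + n_center + n_plus == 25

    def test_zero_margins_identity_element(self):
        assert build_dilation_kernel((0.0, 0.0), 0.1) == (0, 1, 0)

    def test_one_mm_margins_at_half_mm(self):
        assert build_dilation_kernel((1.0, 1.0), 0.5) == (2, 1, 2)

    def test_excess_margin_capped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="mlcmargins.geometry"):
            n_minus, _, _ = build_dilation_kernel((50.0, 0.0), 0.25, max_margin=20.0)
        assert n_minus == 80
        assert any("capped" in r.message for r in caplog.records)


class TestRasterize:
    def test_square_cell_count(self, square10):
        mask = rasterize(square10, 0.25)
        assert mask.n_occupied == 40 * 40

    def test_degenerate_polygon_empty_mask(self, caplog):
        collinear = AperturePolygon(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        with caplog.at_level(logging.WARNING):
            mask = rasterize(collinear, 0.25)
        assert mask.n_occupied == 0

    def test_circle_area_within_one_percent(self):
        mask = rasterize(circle_aperture(50.0), 0.25)
        assert mask.area == pytest.approx(np.pi * 25.0 ** 2, rel=0.01)

    def test_padding_covers_max_margin(self, square10):
        mask = rasterize(square10, 0.25, pad=20.0)
        xs, ys = mask.cell_centers()
        assert xs[0] < -5.0 - 19.5 and xs[-1] > 5.0 + 19.5


class TestDilate:
    def test_zero_margins_identity(self, square10):
        mask = rasterize(square10, 0.25)
        out = dilate(mask, MarginSpec())
        np.testing.assert_array_equal(out.occupancy, mask.occupancy)

    def test_x_margins_extend_x_only(self, square10):
        mask = rasterize(square10, 0.25)
        out = dilate(mask, MarginSpec(x_plus=2.0, x_minus=2.0))
        cols = np.nonzero(out.occupancy.any(axis=0))[0]
        rows = np.nonzero(out.occupancy.any(axis=1))[0]
        assert (cols[-1] - cols[0] + 1) * 0.25 == pytest.approx(14.0)
        assert (rows[-1] - rows[0] + 1) * 0.25 == pytest.approx(10.0)

    def test_extensive(self, rng):
        occ = np.zeros((60, 60), dtype=bool)
        occ[10:50, 10:50] = rng.random((40, 40)) < 0.3
        mask = RasterMask(0.25, (0.0, 0.0), occ)
        out = dilate(mask, MarginSpec(1.0, 0.5, 0.25, 0.75))
        assert np.all(out.occupancy[mask.occupancy])

    def test_monotone_in_each_component(self, square10):
        mask = rasterize(square10, 0.25)
        small = dilate(mask, MarginSpec(x_plus=1.0))
        large = dilate(mask, MarginSpec(x_plus=3.0))
        assert np.all(large.occupancy[small.occupancy])

    def test_axes_commute(self, rng):
        occ = rng.random((30, 30)) < 0.2
        xy = _dilate_1d(_dilate_1d(occ, 2, 5, axis=1), 3, 1, axis=0)
        yx = _dilate_1d(_dilate_1d(occ, 3, 1, axis=0), 2, 5, axis=1)
        np.testing.assert_array_equal(xy, yx)

    def test_matches_naive_shift_or(self, rng):
        occ = np.zeros((25, 25), dtype=bool)
        occ[5:20, 5:20] = rng.random((15, 15)) < 0.25
        mask = RasterMask(0.5, (0.0, 0.0), occ)
        out = dilate(mask, MarginSpec(x_plus=1.0, x_minus=0.5, y_plus=1.5))
        naive = np.zeros_like(occ)
        for bx in range(-1, 3):         # n_minus=1 .. n_plus=2 along x
            for by in range(0, 4):      # n_minus=0 .. n_plus=3 along y
                shifted = np.roll(np.roll(occ, by, axis=0), bx, axis=1)
                if by:
                    shifted[:by, :] = False
                if bx > 0:
                    shifted[:, :bx] = False
                elif bx < 0:
                    shifted[:, bx:] = False
                naive |= shifted
        np.testing.assert_array_equal(out.occupancy, naive)

    def test_grid_auto_extends(self, square10, caplog):
        mask = rasterize(square10, 0.25, pad=1.0)
        with caplog.at_level(logging.WARNING):
            out = dilate(mask, MarginSpec(x_plus=5.0))
        assert out.occupancy.shape[1] > mask.occupancy.shape[1]
        assert out.n_occupied > mask.n_occupied


class TestMaskToPolygon:
    def test_rectangle_gives_four_vertices(self, square10):
        mask = rasterize(square10, 0.25)
        poly = mask_to_polygon(mask)
        assert len(poly.vertices) == 4
        assert poly.area == pytest.approx(mask.area)

    def test_round_trip_reproduces_mask(self, circle50):
        mask = rasterize(circle50, 0.25)
        back = rasterize(mask_to_polygon(mask), 0.25)
        assert back.n_occupied == mask.n_occupied

    def test_round_trip_area_within_boundary_band(self):
        circle = circle_aperture(20.0)
        mask = rasterize(circle, 0.25)
        poly = mask_to_polygon(mask)
        perimeter = np.pi * 20.0
        assert abs(poly.area - circle.area) <= perimeter * 0.25

    def test_two_blobs_keeps_largest(self, caplog):
        occ = np.zeros((20, 20), dtype=bool)
        occ[2:5, 2:5] = True          # 9 cells
        occ[10:18, 10:18] = True      # 64 cells
        with caplog.at_level(logging.WARNING):
            poly = mask_to_polygon(RasterMask(1.0, (0.0, 0.0), occ))
        assert any("components" in r.message for r in caplog.records)
        assert poly.area == pytest.approx(64.0)

    def test_empty_mask_raises(self):
        empty = RasterMask(1.0, (0.0, 0.0), np.zeros((5, 5), dtype=bool))
        with pytest.raises(ApertureVanishedError):
            mask_to_polygon(empty)


def _brute_force_leaves(poly, bank, n_subleaves, dense=0.0625):
    """Independent oracle: dense per-row point sampling, min/max, mean."""
    geom = poly.to_shapely()
    shapely.prepare(geom)
    xmin, _, xmax, _ = poly.bounds
    xs = np.arange(xmin - 1.0, xmax + 1.0, dense)
    left = np.full(bank.n_pairs, np.nan)
    right = np.full(bank.n_pairs, np.nan)
    for k in range(bank.n_pairs):
        lo, _ = bank.pair_edges(k)
        lefts, rights = [], []
        for s in range(n_subleaves):
            y = lo + (s + 0.5) * bank.leaf_width / n_subleaves
            inside = shapely.contains_xy(geom, xs, np.full_like(xs, y))
            if inside.any():
                lefts.append(xs[inside][0])
                rights.append(xs[inside][-1])
        if lefts:
            left[k] = np.mean(lefts)
            right[k] = np.mean(rights)
    return left, right


class TestFitLeaves:
    BANK = BankGeometry(n_pairs=12, leaf_width=5.0)

    def test_rectangle_edges_exact(self):
        rect = AperturePolygon(np.array([[-8.0, -10.0], [8.0, -10.0],
                                         [8.0, 10.0], [-8.0, 10.0]]))
        bank = fit_leaves(rect, self.BANK, n_subleaves=10)
        open_pairs = bank.right - bank.left > 0
        np.testing.assert_allclose(bank.left[open_pairs], -8.0, atol=1e-12)
        np.testing.assert_allclose(bank.right[open_pairs], 8.0, atol=1e-12)

    def test_circle_matches_brute_force(self, circle50):
        bank = fit_leaves(circle50, self.BANK, n_subleaves=10)
        left, right = _brute_force_leaves(circle50, self.BANK, 10)
        good = ~np.isnan(left)
        np.testing.assert_allclose(bank.left[good], left[good], atol=0.125)
        np.testing.assert_allclose(bank.right[good], right[good], atol=0.125)

    def test_random_polygons_match_brute_force(self, rng):
        # interior pairs only: at the polygon's y extremes a chord can be
        # shorter than the oracle's sampling step, so the two methods may
        # disagree on which sub-leaf rows contribute at all
        sub_h = self.BANK.leaf_width / 10
        for _ in range(20):
            poly = random_convex_polygon(rng)
            bank = fit_leaves(poly, self.BANK, n_subleaves=10)
            left, right = _brute_force_leaves(poly, self.BANK, 10)
            _, ymin, _, ymax = poly.bounds
            good = np.zeros(self.BANK.n_pairs, dtype=bool)
            for k in range(self.BANK.n_pairs):
                lo, hi = self.BANK.pair_edges(k)
                good[k] = (lo >= ymin + sub_h) and (hi <= ymax - sub_h)
            good &= ~np.isnan(left)
            assert good.any()
            np.testing.assert_allclose(bank.left[good], left[good], atol=0.125)
            np.testing.assert_allclose(bank.right[good], right[good], atol=0.125)

    def test_single_subleaf_is_center_chord(self, circle50):
        bank = fit_leaves(circle50, self.BANK, n_subleaves=1)
        k = 5  # pair spanning y in [-5, 0], center line y = -2.5
        chord = np.sqrt(25.0 ** 2 - 2.5 ** 2)
        assert bank.left[k] == pytest.approx(-chord, abs=0.05)
        assert bank.right[k] == pytest.approx(chord, abs=0.05)

    def test_outside_bank_all_closed(self, caplog):
        far = AperturePolygon(np.array([[0.0, 200.0], [10.0, 200.0],
                                        [10.0, 210.0], [0.0, 210.0]]))
        with caplog.at_level(logging.WARNING):
            bank = fit_leaves(far, self.BANK)
        assert np.all(bank.left == bank.right)

    def test_row_extents_even_odd(self):
        # concave polygon: a U shape; rows through the notch take global extents
        u = AperturePolygon(np.array([[0, 0], [9, 0], [9, 9], [6, 9], [6, 3],
                                      [3, 3], [3, 9], [0, 9]], dtype=float))
        lo, hi = polygon_row_extents(u.vertices, np.array([6.0]))
        assert lo[0] == pytest.approx(0.0) and hi[0] == pytest.approx(9.0)


class TestSetJaws:
    BANK = BankGeometry(n_pairs=12, leaf_width=5.0)

    def test_zero_margins_at_extrema(self, circle50):
        bank = fit_leaves(circle50, self.BANK)
        bank = set_jaws(bank, MarginSpec(), circle50)
        assert bank.jaw_y_plus == pytest.approx(25.0, abs=1e-6)
        assert bank.jaw_y_minus == pytest.approx(-25.0, abs=1e-6)

    def test_plus_margin_moves_upper_only(self, circle50):
        bank = fit_leaves(circle50, self.BANK)
        bank = set_jaws(bank, MarginSpec(y_plus=3.0), circle50)
        assert bank.jaw_y_plus == pytest.approx(28.0, abs=1e-6)
        assert bank.jaw_y_minus == pytest.approx(-25.0, abs=1e-6)

    def test_equivariant_under_y_shift(self, square10):
        shifted = shift_aperture(square10, (0.0, 7.0))
        b0 = set_jaws(fit_leaves(square10, self.BANK), MarginSpec(), square10)
        b1 = set_jaws(fit_leaves(shifted, self.BANK), MarginSpec(), shifted)
        assert b1.jaw_y_plus - b0.jaw_y_plus == pytest.approx(7.0)
        assert b1.jaw_y_minus - b0.jaw_y_minus == pytest.approx(7.0)


class TestMarginSpec:
    def test_clamping(self, caplog):
        with caplog.at_level(logging.WARNING):
            ms = MarginSpec.clamped(-1.0, 25.0, 2.0, 0.0, max_margin=20.0)
        assert ms.as_tuple() == (0.0, 20.0, 2.0, 0.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(GeometryError):
            MarginSpec(x_plus=-0.5)
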