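"""Shape-descriptor geometry: closed forms, oracles, raster invariances."""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from fazrad.geometry import (
    ContourPolygon,
    DegenerateHullError,
    EmptyMaskError,
    FazMask,
    InternalConsistencyError,
    compactness,
    compute_area,
    convex_hull,
    eccentricity,
    extract_features,
    features_from_polygon,
    feret_diameters,
    polygon_area,
    polygon_perimeter,
    preprocess_mask,
    roundness,
    solidity,
    trace_contour,
)
from fazrad.synthetic import CohortParams, rasterize, sample_contour

from conftest import disk_mask, ellipse_mask, regular_polygon, star_polygon

PX = (0.01, 0.01)


# --------------------------------------------------------------------- masks


class TestPreprocess:
    def test_idempotent_on_clean_disk(self):
        m = disk_mask(20)
        once = preprocess_mask(m)
        twice = preprocess_mask(once)
        assert np.array_equal(once.grid, m.grid)
        assert np.array_equal(twice.grid, once.grid)

    def test_drops_satellite_pixel(self):
        m = disk_mask(10, margin=8)
        g = m.grid.copy()
        g[1, 1] = 1  # isolated speck far from the disk
        cleaned = preprocess_mask(FazMask(g, PX))
        assert np.array_equal(cleaned.grid, m.grid)

    def test_fills_hole_matching_border_flood_fill(self):
        # annulus: disk with a hole; oracle = flood fill of background from
        # the border, anything unreached is interior and must be filled
        m = disk_mask(12, margin=4)
        g = m.grid.copy()
        c = g.shape[0] // 2
        g[c - 2 : c + 2, c - 2 : c + 2] = 0
        filled = preprocess_mask(FazMask(g, PX)).grid

        reached = np.zeros_like(g, dtype=bool)
        q = deque(
            [(i, j) for i in range(g.shape[0]) for j in range(g.shape[1])
             if (i in (0, g.shape[0] - 1) or j in (0, g.shape[1] - 1)) and g[i, j] == 0]
        )
        for i, j in q:
            reached[i, j] = True
        while q:
            i, j = q.popleft()
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < g.shape[0] and 0 <= b < g.shape[1]:
                    if g[a, b] == 0 and not reached[a, b]:
                        reached[a, b] = True
                        q.append((a, b))
        oracle = np.where(reached, 0, 1).astype(np.uint8)
        assert np.array_equal(filled, oracle)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            FazMask(np.zeros((5, 5), dtype=np.uint8), PX)


class TestArea:
    @pytest.mark.parametrize(
        "count,pixel,expected",
        [(100, 0.01, 0.01), (100, 0.1, 1.0)],
    )
    def test_pixel_counting(self, count, pixel, expected):
        side = int(math.isqrt(count))
        grid = np.ones((side, side), dtype=np.uint8)
        assert compute_area(FazMask(grid, (pixel, pixel))) == pytest.approx(expected)

    def test_disk_area_close_to_analytic(self):
        m = disk_mask(60)
        assert compute_area(m) == pytest.approx(math.pi * 0.6**2, rel=0.02)


class TestContour:
    def test_single_pixel_diamond(self):
        g = np.zeros((5, 5), dtype=np.uint8)
        g[2, 2] = 1
        poly = trace_contour(FazMask(g, PX))
        assert len(poly.vertices) == 4
        assert polygon_perimeter(poly) == pytest.approx(2 * math.sqrt(2) * 0.01)

    def test_rectangle_perimeter_converges_with_resolution(self):
        # same physical 1.0 x 0.6 mm rectangle at two raster resolutions
        errs = []
        for n, px in ((50, 0.02), (200, 0.005)):
            h, w = int(0.6 / px), int(1.0 / px)
            g = np.zeros((h + 10, w + 10), dtype=np.uint8)
            g[5 : 5 + h, 5 : 5 + w] = 1
            p = polygon_perimeter(trace_contour(FazMask(g, (px, px))))
            errs.append(abs(p - 3.2))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05 * 3.2

    @pytest.mark.parametrize("radius", [40, 60])
    def test_disk_perimeter_within_2pct(self, radius):
        poly = trace_contour(disk_mask(radius))
        assert polygon_perimeter(poly) == pytest.approx(
            2 * math.pi * radius * 0.01, rel=0.02
        )


# ------------------------------------------------------------------ polygons


class TestPolygonOps:
    def test_unit_square_perimeter(self):
        sq = ContourPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert polygon_perimeter(sq) == pytest.approx(4.0)

    def test_repeated_vertex_adds_no_length(self):
        sq = ContourPolygon(
            np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1]], float)
        )
        assert polygon_perimeter(sq) == pytest.approx(4.0)

    def test_regular_360gon_perimeter_closed_form(self):
        poly = regular_polygon(360)
        assert polygon_perimeter(poly) == pytest.approx(
            2 * 360 * math.sin(math.pi / 360), rel=1e-9
        )
        assert polygon_perimeter(poly) == pytest.approx(2 * math.pi, rel=1e-4)

    def test_hull_of_convex_pentagon_is_itself(self):
        pent = regular_polygon(5)
        hull = convex_hull(pent)
        assert sorted(map(tuple, np.round(hull.vertices, 12))) == sorted(
            map(tuple, np.round(pent.vertices, 12))
        )

    def test_star_hull_is_arm_tip_quadrilateral_brute_force(self):
        star = star_polygon()
        hull = convex_hull(star)
        # brute force on <= 12 vertices: (i, j) is a hull edge iff every
        # other vertex lies on one side of the line through it
        pts = star.vertices
        edge_pts = set()
        n = len(pts)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = pts[j] - pts[i]
                rel = pts - pts[i]
                cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
                if (cross >= -1e-12).all():
                    edge_pts.update([i, j])
        expected = sorted(map(tuple, np.round(pts[sorted(edge_pts)], 12)))
        assert sorted(map(tuple, np.round(hull.vertices, 12))) == expected
        assert len(hull.vertices) == 4

    def test_notched_square_hull_area_is_one(self):
        notched = ContourPolygon(
            np.array(
                [[0, 0], [1, 0], [1, 1], [0.6, 1], [0.5, 0.7], [0.4, 1], [0, 1]],
                float,
            )
        )
        assert polygon_area(convex_hull(notched)) == pytest.approx(1.0)

    def test_collinear_hull_raises(self):
        line = np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]])
        with pytest.raises((DegenerateHullError, ValueError)):
            convex_hull(ContourPolygon(line))


def _brute_force_feret(points: np.ndarray, step_deg: float = 0.05):
    angles = np.deg2rad(np.arange(0, 180, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    widths = (points @ dirs.T).max(axis=0) - (points @ dirs.T).min(axis=0)
    return widths.max(), widths.min()


class TestFeret:
    @pytest.mark.parametrize(
        "poly",
        [
            ContourPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)),
            ContourPolygon(np.array([[0, 0], [2, 0], [2, 0.2], [0, 0.2]], float)),
            regular_polygon(360),
        ],
        ids=["unit-square", "thin-rectangle", "360gon"],
    )
    def test_matches_rotation_scan(self, poly):
        fmax, fmin = feret_diameters(poly)
        bmax, bmin = _brute_force_feret(poly.vertices)
        assert fmax == pytest.approx(bmax, rel=1e-4)
        assert fmin == pytest.approx(bmin, rel=1e-4)

    def test_known_values(self):
        sq = ContourPolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        fmax, fmin = feret_diameters(sq)
        assert fmax == pytest.approx(math.sqrt(2))
        assert fmin == pytest.approx(1.0)
        rect = ContourPolygon(np.array([[0, 0], [2, 0], [2, 0.2], [0, 0.2]], float))
        fmax, fmin = feret_diameters(rect)
        assert fmax == pytest.approx(math.sqrt(4.04), rel=1e-6)
        assert fmin == pytest.approx(0.2)

    def test_circle_has_constant_width(self):
        fmax, fmin = feret_diameters(regular_polygon(360))
        assert fmax == pytest.approx(2.0, rel=1e-3)
        assert fmin == pytest.approx(2.0, rel=1e-3)


# --------------------------------------------------------------- descriptors


class TestDescriptorFormulas:
    def test_solidity_ratio_and_clamp(self):
        assert solidity(0.5, 1.0) == 0.5
        assert solidity(1.0 + 5e-3, 1.0) == 1.0  # raster noise clamped
        with pytest.raises(InternalConsistencyError):
            solidity(1.1, 1.0)

    def test_star_solidity_equals_shoelace_ratio(self):
        star = star_polygon()
        hull = convex_hull(star)
        expected = polygon_area(star) / polygon_area(hull)
        f = features_from_polygon(star)
        assert 0 < expected < 1
        assert f.solidity == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "area,perim,expected",
        [(1.0, 4.0, math.pi / 4), (2.0, 6.0, 4 * math.pi * 2 / 36)],
        ids=["unit-square", "2to1-rectangle"],
    )
    def test_compactness(self, area, perim, expected):
        assert compactness(area, perim) == pytest.approx(expected)

    def test_circle_compactness_is_one(self):
        poly = regular_polygon(3600)
        assert compactness(polygon_area(poly), polygon_perimeter(poly)) == (
            pytest.approx(1.0, abs=1e-5)
        )

    def test_roundness_equals_compactness_for_convex(self):
        pent = regular_polygon(5)
        f = features_from_polygon(pent)
        assert f.roundness == pytest.approx(f.compactness, rel=1e-9)

    def test_star_roundness_exceeds_compactness(self):
        f = features_from_polygon(star_polygon())
        assert f.roundness > f.compactness

    @pytest.mark.parametrize(
        "fmax,fmin,expected",
        [
            (2.0, 2.0, 0.0),
            (4.0, 2.0, math.sqrt(3) / 2),
            (math.sqrt(2), 1.0, math.sqrt(0.5)),
        ],
        ids=["circle", "2to1-ellipse", "unit-square"],
    )
    def test_eccentricity(self, fmax, fmin, expected):
        assert eccentricity(fmax, fmin) == pytest.approx(expected, abs=1e-9)


class TestExtractFeatures:
    def test_rasterized_disk(self):
        f = extract_features(disk_mask(60))
        assert f.solidity >= 0.98
        assert 0.95 <= f.compactness <= 1.02
        assert 0.95 <= f.roundness <= 1.02
        assert f.eccentricity <= 0.15

    def test_rasterized_2to1_ellipse(self):
        f = extract_features(ellipse_mask(80, 40))
        assert f.eccentricity == pytest.approx(math.sqrt(3) / 2, abs=0.05)

    def test_rasterized_star(self):
        # star with deep concavities rasterized at fine resolution
        star = star_polygon(r_outer=0.6, r_inner=0.25)
        n = 160
        yy, xx = np.mgrid[0:n, 0:n]
        pts = np.column_stack(
            [(xx.ravel() - n / 2) * 0.01, (yy.ravel() - n / 2) * 0.01]
        )
        import shapely

        poly = shapely.Polygon(star.vertices)
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1]).reshape(n, n)
        f = extract_features(FazMask(inside.astype(np.uint8), PX))
        assert f.solidity < 0.9
        assert f.roundness >= f.compactness

    def test_translation_invariance(self):
        m = disk_mask(25, margin=20)
        shifted = FazMask(np.roll(m.grid, (7, -5), axis=(0, 1)), PX)
        f0, f1 = extract_features(m), extract_features(shifted)
        assert f0.as_dict() == pytest.approx(f1.as_dict())

    def test_rotation_90_within_tolerance(self):
        params = CohortParams(seed=5)
        rng = np.random.default_rng(5)
        spec = sample_contour("AD", params, rng)
        spec = type(spec)(
            r0=spec.r0, harmonics=spec.harmonics, center=(1.5, 1.5)
        )
        m = rasterize(spec, (256, 256), params.pixel_size_mm)
        rot = FazMask(np.rot90(m.grid).copy(), params.pixel_size_mm)
        f0, f1 = extract_features(m), extract_features(rot)
        for k, v in f0.as_dict().items():
            if k == "eccentricity":
                # compare through the well-conditioned caliper axis ratio
                r0_ = f0.feret_min_mm / f0.feret_max_mm
                r1_ = f1.feret_min_mm / f1.feret_max_mm
                assert r1_ == pytest.approx(r0_, rel=0.03)
            else:
                assert f1.as_dict()[k] == pytest.approx(v, rel=0.03)

    def test_roundness_ge_compactness_on_random_masks(self):
        params = CohortParams(seed=11)
        rng = np.random.default_rng(11)
        for i in range(50):
            spec = sample_contour("AD" if i % 2 else "NC", params, rng)
            spec = type(spec)(r0=spec.r0, harmonics=spec.harmonics, center=(1.5, 1.5))
            f = extract_features(rasterize(spec, (256, 256), params.pixel_size_mm))
            assert f.roundness >= f.compactness - 1e-9
            assert 0 < f.solidity <= 1
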