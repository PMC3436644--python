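"""Voronoi tessellation: geometry, exclusion filter, area statistics."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from striaquant.geometry import GeometryError, SectionGeometry, SomaPointSet
from striaquant.spatial import (
    TessellationResult,
    TessellationSummary,
    VoronoiCell,
    apply_exclusion,
    area_histogram,
    clustering_summary,
    compute_voronoi,
)


def grid_points(xs):
    return np.array([[x, y] for x in xs for y in xs], float)


def random_polygon_section(rng, n_vertices=9, radius=500.0):
    """Star-convex simple polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.4 * radius, radius, n_vertices)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return SectionGeometry(Polygon(pts))


class TestComputeVoronoi:
    def test_regular_grid_equal_cells(self):
        geo = SectionGeometry.rectangle(30, 30)
        res = compute_voronoi(grid_points([5, 15, 25]), geo)
        areas = [c.area_um2 for c in res.cells]
        assert np.allclose(areas, 100.0)
        assert res.summary.cv == pytest.approx(0.0, abs=1e-12)
        assert res.summary.n_included == 9

    @pytest.mark.parametrize("seed", range(5))
    def test_area_conservation_and_disjointness(self, seed):
        rng = np.random.default_rng(seed)
        geo = random_polygon_section(rng)
        minx, miny, maxx, maxy = geo.boundary.bounds
        pts = []
        while len(pts) < 40:
            xy = rng.uniform([minx, miny], [maxx, maxy])
            if geo.boundary.contains(shapely.points(*xy)):
                pts.append(xy)
        res = compute_voronoi(np.array(pts), geo)
        total = sum(c.area_um2 for c in res.cells)
        assert total == pytest.approx(geo.area_um2, rel=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_nearest_seed_property(self, seed, square_section):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, (30, 2))
        res = compute_voronoi(pts, square_section)
        probes = rng.uniform(0, 1000, (100, 2))
        dists = np.linalg.norm(probes[:, None, :] - pts[None, :, :], axis=2)
        order = np.argsort(dists, axis=1)
        for k, probe in enumerate(probes):
            nearest, second = order[k, 0], order[k, 1]
            if np.isclose(dists[k, nearest], dists[k, second]):
                continue  # tie: cell assignment ambiguous by construction
            p = shapely.points(*probe)
            enclosing = [
                i for i, c in enumerate(res.cells) if c.polygon.covers(p)
            ]
            assert nearest in enclosing

    def test_cv_scale_invariance(self, square_section):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1000, (50, 2))
        res1 = compute_voronoi(pts, square_section)
        res2 = compute_voronoi(pts * 3.0, SectionGeometry.rectangle(3000, 3000))
        assert res2.summary.cv == pytest.approx(res1.summary.cv, rel=1e-9)

    def test_too_few_points_rejected(self, square_section):
        with pytest.raises(GeometryError):
            compute_voronoi(np.array([[1.0, 1.0], [2.0, 2.0]]), square_section)

    def test_collinear_points_rejected(self, square_section):
        pts = np.column_stack([np.arange(5.0) * 10 + 1, np.arange(5.0) * 10 + 1])
        with pytest.raises(GeometryError):
            compute_voronoi(pts, square_section)

    def test_duplicate_points_rejected(self, square_section):
        pts = np.array([[10.0, 10.0], [10.0, 10.0], [50.0, 50.0], [80.0, 20.0]])
        with pytest.raises(ValueError):
            compute_voronoi(pts, square_section)

    def test_degenerate_boundary_rejected(self):
        with pytest.raises(GeometryError):
            SectionGeometry(Polygon([(0, 0), (1, 0), (2, 0)]))


def make_result(areas):
    cells = tuple(
        VoronoiCell((float(i), 0.0), Polygon(), float(a), False, False)
        for i, a in enumerate(areas)
    )
    arr = np.asarray(areas, float)
    sd = arr.std(ddof=1) if len(arr) > 1 else np.nan
    return TessellationResult(
        cells=cells,
        summary=TessellationSummary(arr.mean(), sd, sd / arr.mean(), len(arr)),
        boundary_area_um2=float(arr.sum()),
    )


class TestExclusion:
    def test_threshold_rule_is_strict_greater(self):
        res = apply_exclusion(make_result([10_000, 70_000, 59_999]), 60_000)
        included = sorted(res.included_areas())
        assert included == [10_000, 59_999]
        assert [c.excluded for c in res.cells] == [False, True, False]

    def test_no_exclusions_leaves_summary_unchanged(self):
        base = make_result([100.0, 200.0, 300.0])
        res = apply_exclusion(base, 60_000)
        assert res.summary.mean_area == pytest.approx(base.summary.mean_area)
        assert res.summary.n_included == 3

    def test_all_excluded_flags_summary_undefined(self):
        res = apply_exclusion(make_result([70_000, 80_000]), 60_000)
        assert res.summary.n_included == 0
        assert not res.summary.defined
        assert np.isnan(res.summary.mean_area)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            apply_exclusion(make_result([1.0, 2.0]), 0)


class TestHistogram:
    def test_half_open_bins(self):
        edges, counts = area_histogram(make_result([1_000, 2_999, 3_000]), 3_000)
        assert counts.tolist() == [2, 1]
        assert edges.tolist() == [0, 3_000, 6_000]

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_conserve_and_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        areas = rng.uniform(10, 50_000, 200)
        _, counts = area_histogram(make_result(areas), 3_000)
        assert counts.sum() == 200
        _, scaled = area_histogram(make_result(areas * 2), 6_000)
        assert scaled.tolist() == counts.tolist()

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            area_histogram(make_result([1.0]), -1)


class TestClusteringSummary:
    def test_constant_case(self):
        case_df, _ = clustering_summary({("g", "c1"): [make_result([100, 100])],
                                         ("g", "c2"): [make_result([100, 100])]})
        row = case_df.iloc[0]
        assert row.mean_area_um2 == 100
        assert row.sd_area_um2 == 0
        assert row.cv == 0

    def test_sample_sd_convention(self):
        case_df, group_df = clustering_summary(
            {("g", "c"): [make_result([50.0, 150.0])]}
        )
        row = case_df.iloc[0]
        assert row.mean_area_um2 == pytest.approx(100.0)
        assert row.sd_area_um2 == pytest.approx(70.710678, rel=1e-6)
        assert row.cv == pytest.approx(0.70710678, rel=1e-6)
        assert group_df.iloc[0].mean_cv == pytest.approx(row.cv)

    def test_pools_sections_within_case(self):
        # pooling {50} and {150} across two sections equals one section {50,150}
        split = clustering_summary(
            {("g", "c"): [make_result([50.0]), make_result([150.0])]}
        )[0]
        joint = clustering_summary({("g", "c"): [make_result([50.0, 150.0])]})[0]
        assert split.iloc[0].sd_area_um2 == pytest.approx(joint.iloc[0].sd_area_um2)

    def test_empty_case_rejected(self):
        with pytest.raises(ValueError):
            clustering_summary({("g", "c"): []})
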