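"""Geometric indices: closed-form fixtures, brute-force oracles, invariances."""

import numpy as np
import pytest
from scipy.integrate import quad

from capmorph.annotation_io import CapillaryAnnotation, Contour
from capmorph.morphometry import (
    GeometryError,
    MorphometryConfig,
    bm_thickness,
    compute_profile_metrics,
    ec_thickness,
    feret_diameters,
    lumen_radius,
    luminal_enlargement,
    nucleus_area_density,
    pc_coverage,
    polygon_area,
    polygon_perimeter,
    profile_table,
)

from conftest import (
    annulus_annotation,
    arc_band,
    circle_contour,
    ellipse_contour,
    regular_polygon,
    square_contour,
)

CENTER = (3000.0, 3000.0)


def ellipse_perimeter(a: float, b: float) -> float:
    return quad(lambda t: np.hypot(a * np.sin(t), b * np.cos(t)),
                0.0, 2.0 * np.pi, limit=200)[0]


class TestAreaPerimeter:
    def test_unit_square(self):
        sq = square_contour(1.0)
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_perimeter(sq) == pytest.approx(4.0)

    def test_orientation_independence(self):
        assert polygon_area(square_contour(1.0, reverse=True)) == pytest.approx(1.0)

    def test_scale_applies(self):
        sq = square_contour(2.0, scale=10.0)
        assert polygon_area(sq) == pytest.approx(400.0)
        assert polygon_perimeter(sq) == pytest.approx(80.0)

    def test_regular_polygon_closed_forms(self):
        # inscribed 512-gon: area (n/2) r^2 sin(2 pi/n), perimeter 2 n r sin(pi/n)
        n, r = 512, 100.0
        c = circle_contour(r, n)
        assert polygon_area(c) == pytest.approx((n / 2) * r**2 * np.sin(2 * np.pi / n),
                                                rel=1e-12)
        assert polygon_area(c) == pytest.approx(np.pi * r**2, rel=1e-4)
        assert polygon_perimeter(c) == pytest.approx(2 * n * r * np.sin(np.pi / n),
                                                     rel=1e-12)
        assert polygon_perimeter(c) == pytest.approx(2 * np.pi * r, rel=1e-4)

    def test_open_polyline_perimeter(self):
        line = Contour(np.array([[0.0, 0.0], [3.0, 4.0]]), closed=False)
        assert polygon_perimeter(line) == pytest.approx(5.0)

    def test_errors(self):
        with pytest.raises(GeometryError):
            polygon_area(Contour(np.array([[0.0, 0.0], [1.0, 1.0]]), closed=False))
        with pytest.raises(GeometryError):
            polygon_perimeter(Contour(np.array([[0.0, 0.0]]), closed=False))


class TestFeret:
    def test_circle_ratio_one(self):
        _, _, ratio = feret_diameters(circle_contour(100.0))
        assert ratio == pytest.approx(1.0, abs=1e-3)

    def test_axis_aligned_ellipse(self):
        fmin, fmax, ratio = feret_diameters(ellipse_contour(1.3, 1.0))
        assert fmin == pytest.approx(2.0, rel=1e-4)
        assert fmax == pytest.approx(2.6, rel=1e-4)
        assert ratio == pytest.approx(1.3, rel=1e-3)

    def test_random_convex_polygons_match_projection_oracle(self, rng):
        # oracle: caliper widths over 3600 projection directions
        angles = np.linspace(0.0, np.pi, 3600, endpoint=False)
        dirs = np.column_stack([np.cos(angles), np.sin(angles)])
        for _ in range(20):
            pts = rng.normal(size=(30, 2)) * rng.uniform(1, 10, size=2)
            from scipy.spatial import ConvexHull
            hull_pts = pts[ConvexHull(pts).vertices]
            contour = Contour(hull_pts, closed=True)
            proj = hull_pts @ dirs.T
            widths = proj.max(axis=0) - proj.min(axis=0)
            fmin, fmax, ratio = feret_diameters(contour)
            # the sampled oracle can only overestimate the min caliper width
            # (and underestimate the max diameter) by O(angular step)
            assert fmin <= widths.min() * (1 + 1e-12)
            assert fmax >= widths.max() * (1 - 1e-12)
            assert fmin == pytest.approx(widths.min(), rel=2e-3)
            assert fmax == pytest.approx(widths.max(), rel=2e-3)
            assert ratio >= 1.0

    def test_collinear_contour_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(GeometryError):
            feret_diameters(Contour(pts, closed=True))


class TestLumenRadius:
    def test_circle(self):
        ann = annulus_annotation(r0=1000.0)
        assert lumen_radius(ann) == pytest.approx(1000.0, rel=1e-4)

    def test_square_lumen(self):
        ann = annulus_annotation()
        ann.lumen = square_contour(2000.0, center=CENTER)
        # 2 * (2000^2) / 8000 = 1000
        assert lumen_radius(ann) == pytest.approx(1000.0)

    def test_ellipse_against_quadrature(self):
        a, b = 2000.0, 1000.0
        ann = annulus_annotation()
        ann.lumen = ellipse_contour(a, b, n=2048, center=CENTER)
        expected = 2 * np.pi * a * b / ellipse_perimeter(a, b)
        assert expected == pytest.approx(1297.0, abs=1.0)  # ~ 2A/C
        assert lumen_radius(ann) == pytest.approx(expected, rel=1e-4)


class TestThickness:
    def test_ec_annulus_consistent(self, annulus):
        # ring 2000 -> 2500: 2 pi (r1^2 - r0^2) / (2 pi (r1 + r0)) = 500
        assert ec_thickness(annulus, "consistent") == pytest.approx(500.0, rel=1e-4)

    def test_ec_annulus_as_printed_diverges(self, annulus):
        # literal formula keeps the full abluminal disc area: r1^2 / (r1 + r0)
        expected = 2500.0**2 / 4500.0
        assert ec_thickness(annulus, "as_printed") == pytest.approx(expected, rel=1e-4)
        assert ec_thickness(annulus, "as_printed") == pytest.approx(1388.9, abs=0.5)

    def test_bm_annulus_consistent(self, annulus):
        assert bm_thickness(annulus, "consistent") == pytest.approx(300.0, rel=1e-4)

    def test_bm_as_printed_negative_on_annulus(self, annulus):
        # (r2^2 - r1^2 - r0^2) / (r0 + r1 + r2) < 0 with r0=2000,r1=2500,r2=2800
        expected = (2800.0**2 - 2500.0**2 - 2000.0**2) / 7300.0
        assert expected < 0
        assert bm_thickness(annulus, "as_printed") == pytest.approx(expected, rel=1e-4)

    def test_eccentric_annulus_matches_polygon_difference_oracle(self):
        from shapely.geometry import Polygon

        ann = annulus_annotation()
        ann.lumen = circle_contour(2000.0, center=(3200.0, 3000.0))
        ring = Polygon(ann.ec_abluminal.points).difference(
            Polygon(ann.lumen.points))
        expected = 2.0 * ring.area / (
            Polygon(ann.ec_abluminal.points).exterior.length
            + Polygon(ann.lumen.points).exterior.length)
        assert ec_thickness(ann, "consistent") == pytest.approx(expected, rel=1e-3)

    def test_bm_pericyte_subtraction_algebra(self, annulus):
        # adding a pericyte of area A_PC lowers the consistent BM thickness by
        # exactly 2 A_PC / (C_BM + C_EC)
        base = bm_thickness(annulus, "consistent")
        pc = arc_band(2550.0, 2750.0, 0.3, 1.1)
        annulus.pericytes.append(pc)
        a_pc = polygon_area(pc)
        denom = (polygon_perimeter(annulus.bm_outer)
                 + polygon_perimeter(annulus.ec_abluminal))
        assert bm_thickness(annulus, "consistent") == pytest.approx(
            base - 2.0 * a_pc / denom, rel=1e-9)

    def test_non_nested_contours_rejected(self, annulus):
        annulus.lumen = circle_contour(2600.0, center=CENTER)
        with pytest.raises(GeometryError):
            ec_thickness(annulus, "consistent")


class TestPcCoverage:
    def test_single_quarter_arc(self, annulus):
        annulus.pericytes = [arc_band(2550.0, 2750.0, 0.0, np.pi / 2)]
        assert pc_coverage(annulus) == pytest.approx(0.25, abs=2e-3)

    def test_disjoint_arcs_additive(self, annulus):
        annulus.pericytes = [
            arc_band(2550.0, 2750.0, 0.0, np.pi / 3),          # 60 deg
            arc_band(2550.0, 2750.0, np.pi, np.pi + np.pi / 6),  # 30 deg
        ]
        assert pc_coverage(annulus) == pytest.approx(0.25, abs=2e-3)

    def test_overlapping_arcs_merged_not_summed(self, annulus):
        annulus.pericytes = [
            arc_band(2550.0, 2750.0, 0.0, np.pi / 3),
            arc_band(2550.0, 2750.0, np.pi / 6, np.pi / 2),
        ]
        # union [0, 90deg] = 0.25, not 60/360 + 60/360
        assert pc_coverage(annulus) == pytest.approx(0.25, abs=2e-3)

    def test_random_arcs_match_interval_union_oracle(self, rng, annulus):
        for _ in range(10):
            k = int(rng.integers(1, 5))
            starts = rng.uniform(0, 2 * np.pi, size=k)
            widths = rng.uniform(0.1, 2.0, size=k)
            annulus.pericytes = [
                arc_band(2550.0, 2750.0, s, s + w)
                for s, w in zip(starts, widths)
            ]
            # oracle: union length of angular intervals on the circle
            grid = np.linspace(0, 2 * np.pi, 720000, endpoint=False)
            covered = np.zeros_like(grid, dtype=bool)
            for s, w in zip(starts, widths):
                covered |= ((grid - s) % (2 * np.pi)) <= w
            expected = covered.mean()
            assert pc_coverage(annulus) == pytest.approx(expected, abs=3e-3)

    def test_wrapping_arc(self, annulus):
        annulus.pericytes = [arc_band(2550.0, 2750.0, -np.pi / 4, np.pi / 4)]
        assert pc_coverage(annulus) == pytest.approx(0.25, abs=2e-3)

    def test_no_pericytes(self, annulus):
        assert pc_coverage(annulus) == 0.0

    def test_coverage_in_unit_interval(self, rng, annulus):
        annulus.pericytes = [arc_band(2550.0, 2750.0, 0.0, 2 * np.pi * 0.999)]
        assert 0.0 <= pc_coverage(annulus) <= 1.0


class TestDensityAndEnlargement:
    def test_no_nucleus_zero(self, annulus):
        assert nucleus_area_density(annulus) == 0.0

    def test_nucleus_fraction_of_ring(self, annulus):
        nuc = arc_band(2100.0, 2400.0, 0.0, 1.0, center=CENTER)
        annulus.nuclei = [nuc]
        ring = (polygon_area(annulus.ec_abluminal)
                - polygon_area(annulus.lumen))
        expected = 100.0 * polygon_area(nuc) / ring
        assert nucleus_area_density(annulus) == pytest.approx(expected, rel=1e-9)

    def test_nucleus_exceeding_ring_rejected(self, annulus):
        annulus.nuclei = [circle_contour(2450.0, center=CENTER)]
        with pytest.raises(GeometryError):
            nucleus_area_density(annulus)

    def test_no_projections_zero(self, annulus):
        assert luminal_enlargement(annulus) == 0.0

    def test_projection_excess_percentage(self, annulus):
        c_lum = polygon_perimeter(annulus.lumen)
        length = 0.15 * c_lum
        annulus.projections = [Contour(
            np.array([[3000.0 + 2000.0, 3000.0],
                      [3000.0 + 2000.0 - length, 3000.0]]), closed=False)]
        assert luminal_enlargement(annulus) == pytest.approx(15.0, rel=1e-6)


class TestProfileMetrics:
    def test_annulus_fixture_values(self, annulus):
        m = compute_profile_metrics(annulus)
        assert m.lumen_radius_nm == pytest.approx(2000.0, rel=1e-3)
        assert m.ec_thickness_nm == pytest.approx(500.0, rel=1e-3)
        assert m.bm_thickness_nm == pytest.approx(300.0, rel=1e-3)
        assert not m.excluded and m.exclusion_reason == "none"

    def test_oblique_ellipse_excluded_but_measured(self):
        ann = annulus_annotation()
        for name, r in (("lumen", 2000.0), ("ec_abluminal", 2500.0),
                        ("bm_outer", 2800.0)):
            setattr(ann, name, ellipse_contour(1.3 * r, r, center=CENTER))
        m = compute_profile_metrics(ann)
        assert m.excluded and m.exclusion_reason == "oblique_section"
        assert m.aspect_ratio == pytest.approx(1.3, rel=1e-3)
        assert np.isfinite(m.bm_thickness_nm)

    def test_invalid_geometry_flagged(self, annulus):
        annulus.lumen = circle_contour(2600.0, center=CENTER)
        m = compute_profile_metrics(annulus)
        assert m.excluded and m.exclusion_reason == "invalid_geometry"
        assert np.isnan(m.lumen_radius_nm)

    def test_exclusion_filter_bookkeeping(self):
        # 20 profiles, 6 of them elongated beyond the 1.2 cutoff
        anns = []
        for i in range(20):
            e = 1.5 if i < 6 else 1.05
            ann = annulus_annotation(micrograph_id=f"m{i}")
            for name, r in (("lumen", 2000.0), ("ec_abluminal", 2500.0),
                            ("bm_outer", 2800.0)):
                setattr(ann, name,
                        ellipse_contour(e * r, r, center=CENTER))
            anns.append(ann)
        df = profile_table(anns)
        assert int(df["excluded"].sum()) == 6
        assert (df.loc[df["excluded"], "exclusion_reason"]
                == "oblique_section").all()

    def test_dual_route_against_shapely_oracle(self, rng):
        # independent re-computation of area-derived indices via shapely
        from shapely.geometry import LineString, Polygon

        from conftest import random_annotation

        for i in range(25):
            ann = random_annotation(rng, f"m{i}", n=96)
            s = ann.lumen.scale_nm_per_px
            lum, ec, bm = (Polygon(c.points) for c in
                           (ann.lumen, ann.ec_abluminal, ann.bm_outer))
            m = compute_profile_metrics(ann)
            assert lumen_radius(ann) == pytest.approx(
                2 * lum.area * s / lum.exterior.length, rel=1e-9)
            assert ec_thickness(ann) == pytest.approx(
                2 * (ec.area - lum.area) * s
                / (ec.exterior.length + lum.exterior.length), rel=1e-9)
            a_pc = sum(Polygon(p.points).area for p in ann.pericytes)
            assert bm_thickness(ann) == pytest.approx(
                2 * (bm.area - ec.area - a_pc) * s
                / (bm.exterior.length + ec.exterior.length), rel=1e-9)
            if ann.projections:
                total = sum(LineString(p.points).length
                            for p in ann.projections)
                assert luminal_enlargement(ann) == pytest.approx(
                    100 * total / lum.exterior.length, rel=1e-9)


class TestInvariances:
    @pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, rng, s):
        from conftest import random_annotation

        ann = random_annotation(rng, "m", n=96)
        m0 = compute_profile_metrics(ann)

        def rescale(c):
            return Contour(points=c.points * s, closed=c.closed,
                           scale_nm_per_px=c.scale_nm_per_px / s)

        ann2 = CapillaryAnnotation(
            micrograph_id="m", subject_id="s", biopsy_id="b",
            group=ann.group, rater_id="A",
            lumen=rescale(ann.lumen), ec_abluminal=rescale(ann.ec_abluminal),
            bm_outer=rescale(ann.bm_outer),
            pericytes=[rescale(c) for c in ann.pericytes],
            nuclei=[rescale(c) for c in ann.nuclei],
            projections=[rescale(c) for c in ann.projections],
        )
        m1 = compute_profile_metrics(ann2)
        for fieldname in ("lumen_radius_nm", "ec_thickness_nm",
                          "bm_thickness_nm", "pc_coverage",
                          "nucleus_area_density_pct",
                          "luminal_enlargement_pct", "aspect_ratio"):
            assert getattr(m1, fieldname) == pytest.approx(
                getattr(m0, fieldname), rel=1e-9), fieldname

    def test_rigid_motion_invariance(self, rng):
        from conftest import random_annotation

        ann = random_annotation(rng, "m", n=96)
        m0 = compute_profile_metrics(ann)
        phi = 1.1
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        shift = np.array([123.0, -77.0])

        def move(c):
            return Contour(points=c.points @ rot.T + shift, closed=c.closed,
                           scale_nm_per_px=c.scale_nm_per_px)

        ann2 = CapillaryAnnotation(
            micrograph_id="m", subject_id="s", biopsy_id="b",
            group=ann.group, rater_id="A",
            lumen=move(ann.lumen), ec_abluminal=move(ann.ec_abluminal),
            bm_outer=move(ann.bm_outer),
            pericytes=[move(c) for c in ann.pericytes],
            nuclei=[move(c) for c in ann.nuclei],
            projections=[move(c) for c in ann.projections],
        )
        m1 = compute_profile_metrics(ann2)
        for fieldname in ("lumen_radius_nm", "ec_thickness_nm",
                          "bm_thickness_nm", "pc_coverage",
                          "nucleus_area_density_pct",
                          "luminal_enlargement_pct", "aspect_ratio"):
            assert getattr(m1, fieldname) == pytest.approx(
                getattr(m0, fieldname), rel=1e-3), fieldname

    def test_bm_thickness_monotone_in_outer_contour(self, annulus):
        values = [
            bm_thickness(annulus_annotation(r2=r2), "consistent")
            for r2 in (2700.0, 2800.0, 2900.0, 3100.0)
        ]
        assert np.all(np.diff(values) > 0)
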