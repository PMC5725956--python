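"""Shared shape descriptors against analytic and brute-force oracles."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

import organmorph as om
from organmorph.contour import Contour
from organmorph.descriptors import Arc, max_transverse_diameter, signed_curvature_profile
from organmorph.errors import ArcTooShortError

from conftest import circle_contour, egg_contour, ellipse_contour


def shapely_max_chord(vertices: np.ndarray, n_levels: int = 10_000) -> float:
    """Independent dense chord-scan oracle (shapely line-polygon intersection)."""
    poly = Polygon(vertices)
    y0, y1 = vertices[:, 1].min(), vertices[:, 1].max()
    x0, x1 = vertices[:, 0].min() - 1, vertices[:, 0].max() + 1
    best = 0.0
    for y in np.linspace(y0 + 1e-9, y1 - 1e-9, n_levels):
        cut = poly.intersection(LineString([(x0, y), (x1, y)]))
        if cut.is_empty:
            continue
        geoms = getattr(cut, "geoms", [cut])
        for g in geoms:
            if g.geom_type == "LineString":
                best = max(best, g.length)
    return best


class TestBasicSize:
    def test_unit_square(self):
        v = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        s = om.basic_size(Contour(v, calibrated=True))
        assert s.area == pytest.approx(1.0)
        assert s.perimeter == pytest.approx(4.0)
        assert s.height == pytest.approx(1.0)
        assert s.max_tr_diam == pytest.approx(1.0, rel=1e-3)
        assert s.min_cnt_tr == pytest.approx(0.5, rel=1e-2)

    def test_vertical_ellipse(self):
        s = om.basic_size(ellipse_contour(2.0, 1.0))
        assert s.height == pytest.approx(4.0, rel=1e-3)
        assert s.max_tr_diam == pytest.approx(2.0, rel=1e-3)
        assert s.area == pytest.approx(2 * np.pi, rel=0.005)

    def test_random_convex_polygon_vs_chord_oracle(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(42)
        pts = rng.normal(size=(200, 2)) * [1.0, 1.7]
        hull = ConvexHull(pts)
        c = om.smooth_resample(Contour(pts[hull.vertices], calibrated=True),
                               0.0, 1000)
        s = om.basic_size(c)
        oracle = shapely_max_chord(c.vertices, n_levels=2000)
        assert s.max_tr_diam == pytest.approx(oracle, rel=0.002)

    def test_chord_geometry_consistency(self):
        s = om.basic_size(egg_contour(1.0, 2.0, 0.8))
        (xa, ya), (xb, yb) = s.chord_endpoints
        assert ya == yb  # horizontal chord
        assert xb - xa == pytest.approx(s.max_tr_diam, rel=1e-9)
        assert s.min_cnt_tr <= s.max_tr_diam / 2 + 1e-9


class TestSymmetry:
    def test_circle_fully_symmetric(self):
        s = om.basic_size(circle_contour(1.0))
        ver, tr = om.symmetry(s)
        assert ver == pytest.approx(0.5, abs=0.005)
        assert tr == pytest.approx(0.5, abs=0.005)

    def test_egg_widest_third_from_apex(self):
        # widest chord by construction at 1/3 of the height from the apex
        s = om.basic_size(egg_contour(1.0, 2.0, 0.8))
        ver, _ = om.symmetry(s)
        assert ver == pytest.approx(1.0 / 3.0, rel=0.02)

    def test_from_base_complements(self):
        s = om.basic_size(egg_contour(1.0, 2.0, 0.8))
        ver_apex, _ = om.symmetry(s, from_base=False)
        ver_base, _ = om.symmetry(s, from_base=True)
        assert ver_apex + ver_base == pytest.approx(1.0, abs=1e-9)

    def test_mirror_symmetric_tr(self):
        _, tr = om.symmetry(om.basic_size(ellipse_contour(1.5, 1.0)))
        assert tr == pytest.approx(0.5, rel=0.01)


class TestShapeScores:
    def test_circle(self):
        c = circle_contour(1.0)
        sc = om.shape_scores(c, om.basic_size(c))
        assert sc.sh_idx == pytest.approx(1.0, rel=0.01)
        assert sc.circ == pytest.approx(1.0, rel=0.01)
        assert sc.ellipse_major == pytest.approx(2.0, rel=0.01)
        assert sc.ellipse_minor == pytest.approx(2.0, rel=0.01)

    def test_two_to_one_ellipse(self):
        c = ellipse_contour(2.0, 1.0)
        sc = om.shape_scores(c, om.basic_size(c))
        assert sc.sh_idx == pytest.approx(2.0, rel=0.01)
        assert sc.ellipse_major / sc.ellipse_minor == pytest.approx(2.0, rel=0.01)

    def test_star_less_circular_than_hull(self):
        from scipy.spatial import ConvexHull

        ang = np.pi / 2 + np.arange(10) * np.pi / 5
        radii = np.where(np.arange(10) % 2 == 0, 1.0, 0.4)
        star = Contour(np.column_stack([radii * np.cos(ang), radii * np.sin(ang)]),
                       calibrated=True)
        star_r = om.smooth_resample(star, 0.0, 1000)
        sc_star = om.shape_scores(star_r, om.basic_size(star_r))
        hull_v = star.vertices[ConvexHull(star.vertices).vertices]
        hull = om.smooth_resample(Contour(hull_v, calibrated=True), 0.0, 1000)
        sc_hull = om.shape_scores(hull, om.basic_size(hull))
        assert sc_star.circ < 0.5
        assert sc_star.circ < sc_hull.circ

    def test_scale_invariance(self):
        c = egg_contour(1.0, 2.0, 0.8)
        s = om.basic_size(c)
        sc = om.shape_scores(c, s)
        big = Contour(c.vertices * 7.3, calibrated=True)
        sb = om.basic_size(big)
        scb = om.shape_scores(big, sb)
        for attr in ("ver_sym", "tr_sym", "sh_idx", "circ"):
            assert getattr(scb, attr) == pytest.approx(getattr(sc, attr), rel=1e-6)
        assert sb.area == pytest.approx(s.area * 7.3**2, rel=1e-9)
        assert sb.perimeter == pytest.approx(s.perimeter * 7.3, rel=1e-9)

    def test_circ_bounded_by_isoperimetric_inequality(self):
        from organmorph.synthetic import make_blob

        for seed in range(100):
            fx = make_blob(roughness=0.15, seed=seed, pixels_per_cm=100.0)
            c = om.smooth_resample(Contour(fx.boundary_cm, calibrated=True), 0.0, 600)
            sc = om.shape_scores(c, om.basic_size(c))
            assert sc.circ <= 1.0 + 1e-6


class TestExtremeArc:
    def test_circle_subtended_angle(self):
        arc = om.extreme_arc(circle_contour(1.0), "apex", 0.05)
        span = np.deg2rad(18.0)
        a0, a1 = arc.vertices[0], arc.vertices[-1]
        angle = np.arccos(np.clip(a0 @ a1, -1, 1))
        assert np.rad2deg(angle) == pytest.approx(18.0, abs=1.0)
        assert np.isclose(arc.vertices[arc.anchor_index, 1],
                          1.0, atol=1e-3)  # anchored at the apex

    def test_vertex_count(self):
        arc = om.extreme_arc(circle_contour(1.0, n=1000), "base", 0.2)
        assert len(arc.vertices) == 200

    def test_base_vs_apex_disjoint(self):
        c = ellipse_contour(2.0, 1.0)
        top = om.extreme_arc(c, "base", 0.05)
        bot = om.extreme_arc(c, "apex", 0.05)
        assert top.vertices[:, 1].max() < 0 < bot.vertices[:, 1].min()


class TestMeanCurvature:
    def test_circular_arc(self):
        arc = om.extreme_arc(circle_contour(2.0), "apex", 0.1)
        k = om.mean_curvature(arc)
        assert k.kappa_mean == pytest.approx(0.5, rel=0.02)

    def test_straight_segment(self):
        x = np.linspace(0, 1, 50)
        arc = Arc(np.column_stack([x, np.zeros_like(x)]), anchor_index=25)
        assert om.mean_curvature(arc).kappa_mean == pytest.approx(0.0, abs=1e-3)

    def test_parabola_matches_integral_oracle(self):
        x = np.linspace(-0.1, 0.1, 101)
        arc = Arc(np.column_stack([x, x**2]), anchor_index=50)
        k = om.mean_curvature(arc)
        kappa = 2.0 / (1.0 + 4.0 * x**2) ** 1.5
        assert k.kappa_mean == pytest.approx(kappa.mean(), rel=0.03)

    def test_short_arc_rejected(self):
        with pytest.raises(ArcTooShortError):
            om.mean_curvature(Arc(np.zeros((5, 2)), anchor_index=2))

    def test_curvature_scales_inversely(self):
        arc = om.extreme_arc(ellipse_contour(2.0, 1.0), "apex", 0.05)
        big = Arc(arc.vertices * 3.0, anchor_index=arc.anchor_index)
        assert om.mean_curvature(big).kappa_mean == pytest.approx(
            om.mean_curvature(arc).kappa_mean / 3.0, rel=1e-9
        )

    @pytest.mark.parametrize("ab", [(1.0, 1.0), (1.5, 1.0), (2.0, 0.8)])
    def test_turning_angle_conservation(self, ab):
        # for a convex closed contour, mean |kappa| * perimeter ~ 2 pi
        c = ellipse_contour(*ab)
        k = np.abs(signed_curvature_profile(c))
        assert k.mean() * c.perimeter() == pytest.approx(2 * np.pi, rel=0.05)


class TestSignedCurvature:
    def test_convex_contour_all_positive(self):
        k = signed_curvature_profile(ellipse_contour(1.5, 1.0))
        assert (k > 0).all()

    def test_notched_contour_has_negative_run(self):
        t = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        r = 1.0 - 0.2 * np.exp(-((np.arctan2(np.sin(t - np.pi / 2),
                                             np.cos(t - np.pi / 2))) ** 2) / 0.02)
        c = om.smooth_resample(
            Contour(np.column_stack([r * np.cos(t), r * np.sin(t)]),
                    calibrated=True), 0.0, 1000)
        assert (signed_curvature_profile(c) < 0).any()


def test_max_transverse_diameter_refinement_beats_coarse_scan():
    c = ellipse_contour(2.0, 1.0)
    length, xa, xb, y = max_transverse_diameter(c, n_scan=256)
    assert length == pytest.approx(2.0, rel=0.002)
    assert abs(y) < 0.05  # widest chord at the equator
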