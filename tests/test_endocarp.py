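"""Endocarp vertical-position descriptors against exhaustive oracles."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import polygon2mask

import organmorph as om
from organmorph.contour import Contour
from organmorph.endocarp import min_enclosing_circle
from organmorph.synthetic import make_grooved_disc

from conftest import circle_contour, ellipse_contour, measure_fixture


def _poly_contour(xy, n_out=1000):
    return om.smooth_resample(Contour(np.asarray(xy, float), calibrated=True),
                              0.0, n_out)


def brute_force_mec(points):
    """O(n^3) exhaustive minimum enclosing circle over pairs and triples."""
    from organmorph.endocarp import _circumcircle

    pts = np.asarray(points, float)
    n = len(pts)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2
            r = np.hypot(*(pts[i] - pts[j])) / 2
            if np.hypot(*(pts - c).T).max() <= r + 1e-9:
                if best is None or r < best[1]:
                    best = (c, r)
    if best is not None:
        return best
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                cc = _circumcircle(pts[i], pts[j], pts[k])
                if cc is None:
                    continue
                c, r = cc
                if np.hypot(*(pts - c).T).max() <= r * (1 + 1e-12) + 1e-12:
                    if best is None or r < best[1]:
                        best = (c, r)
    return best


def edt_inscribed_diameter(vertices, n_grid=2000):
    """Grid oracle: distance transform of a rasterized polygon."""
    v = np.asarray(vertices, float)
    x0, y0 = v.min(axis=0) - 0.05
    x1, y1 = v.max(axis=0) + 0.05
    scale = n_grid / max(x1 - x0, y1 - y0)
    rows = (v[:, 1] - y0) * scale
    cols = (v[:, 0] - x0) * scale
    shape = (int(np.ceil((y1 - y0) * scale)) + 1, int(np.ceil((x1 - x0) * scale)) + 1)
    mask = polygon2mask(shape, np.column_stack([rows, cols]))
    return 2.0 * ndimage.distance_transform_edt(mask).max() / scale


class TestAreaConvexity:
    def test_convex_polygon_is_one(self):
        assert om.area_convexity(ellipse_contour(1.5, 1.0)) == pytest.approx(1.0, abs=1e-6)

    def test_plus_sign_five_sevenths(self):
        xy = [(-0.5, -1.5), (0.5, -1.5), (0.5, -0.5), (1.5, -0.5), (1.5, 0.5),
              (0.5, 0.5), (0.5, 1.5), (-0.5, 1.5), (-0.5, 0.5), (-1.5, 0.5),
              (-1.5, -0.5), (-0.5, -0.5)]
        c = Contour(np.array(xy), calibrated=True)
        assert om.area_convexity(c) == pytest.approx(5.0 / 7.0, abs=1e-6)

    def test_five_pointed_star_closed_form(self):
        R, r = 1.0, 0.4
        ang = np.pi / 2 + np.arange(10) * np.pi / 5
        radii = np.where(np.arange(10) % 2 == 0, R, r)
        c = Contour(np.column_stack([radii * np.cos(ang), radii * np.sin(ang)]),
                    calibrated=True)
        star_area = 5.0 * R * r * np.sin(np.pi / 5)
        hull_area = 2.5 * R**2 * np.sin(2 * np.pi / 5)  # pentagon of the 5 tips
        assert om.area_convexity(c) == pytest.approx(star_area / hull_area, rel=0.01)

    def test_scale_invariant(self):
        fx = make_grooved_disc(1.0, 0.1, 8)
        c = _poly_contour(fx.boundary_cm)
        big = Contour(c.vertices * 123.4, calibrated=True)
        assert om.area_convexity(big) == pytest.approx(om.area_convexity(c), rel=1e-9)


class TestCentreDistances:
    def test_circle(self):
        dmin, dmax = om.centre_distances(circle_contour(1.0))
        assert dmin == pytest.approx(1.0, rel=0.005)
        assert dmax == pytest.approx(1.0, rel=0.005)

    def test_ellipse(self):
        dmin, dmax = om.centre_distances(ellipse_contour(2.0, 1.0))
        assert dmin == pytest.approx(1.0, rel=0.01)
        assert dmax == pytest.approx(2.0, rel=0.01)

    def test_blob_matches_dense_sampling_oracle(self):
        from organmorph.synthetic import make_blob

        fx = make_blob(roughness=0.15, seed=3)
        c = _poly_contour(fx.boundary_cm)
        dmin, dmax = om.centre_distances(c)
        centroid = c.centroid()
        dense = om.smooth_resample(c, 0.0, 100_000).vertices
        d = np.hypot(*(dense - centroid).T)
        assert dmin == pytest.approx(d.min(), rel=0.001)
        assert dmax == pytest.approx(d.max(), rel=0.001)


class TestInscribedCircle:
    def test_square(self):
        sq = Contour(np.array([[0, 0], [2, 0], [2, 2], [0, 2.0]]), calibrated=True)
        assert om.inscribed_circle_diameter(sq) == pytest.approx(2.0, rel=0.005)

    def test_circle(self):
        assert om.inscribed_circle_diameter(circle_contour(1.0)) == \
            pytest.approx(2.0, rel=0.005)

    def test_l_shape_matches_grid_oracle(self):
        xy = np.array([[0, 0], [2, 0], [2, 2], [1, 2], [1, 1], [0, 1.0]])
        c = Contour(xy, calibrated=True)
        oracle = edt_inscribed_diameter(xy, n_grid=2000)
        assert om.inscribed_circle_diameter(c) == pytest.approx(oracle, rel=0.005)

    def test_centre_clearance_equals_radius(self):
        fx = make_grooved_disc(1.0, 0.08, 6)
        c = _poly_contour(fx.boundary_cm)
        d = om.inscribed_circle_diameter(c)
        assert d == pytest.approx(2 * (1.0 - 0.08), rel=0.01)


class TestBoundingCircle:
    def test_equilateral_triangle(self):
        t = Contour(np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]), calibrated=True)
        assert om.bounding_circle_diameter(t) == pytest.approx(2 / np.sqrt(3), abs=1e-6)

    def test_square_diagonal(self):
        sq = Contour(np.array([[0, 0], [2, 0], [2, 2], [0, 2.0]]), calibrated=True)
        assert om.bounding_circle_diameter(sq) == pytest.approx(2 * np.sqrt(2), abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        pts = np.random.default_rng(seed).normal(size=(50, 2))
        c, r = min_enclosing_circle(pts)
        oc, orr = brute_force_mec(pts)
        assert r == pytest.approx(orr, abs=1e-9)
        assert np.hypot(*(c - oc)) < 1e-9

    def test_all_vertices_enclosed(self):
        pts = np.random.default_rng(99).normal(size=(200, 2))
        c, r = min_enclosing_circle(pts)
        assert np.hypot(*(pts - c).T).max() <= r + 1e-9


class TestGrooveDepths:
    def test_convex_shape_no_pockets(self):
        gmean, gmax, count = om.groove_depths(ellipse_contour(1.5, 1.0))
        assert (gmean, gmax, count) == (0.0, 0.0, 0)

    def test_notched_disc_depth(self):
        # disc with one triangular notch; pocket depth is measured from the
        # hull chord spanning the notch mouth, so the radial cut is deepened
        # by the chord's sagitta to make the perpendicular depth exactly 0.3
        half_w = 0.35
        radial = 0.3 + (1.0 - np.cos(half_w))
        t = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        d = np.arctan2(np.sin(t - np.pi / 2), np.cos(t - np.pi / 2))
        notch = np.clip(1 - np.abs(d) / half_w, 0, None) * radial
        r = 1.0 - notch
        c = _poly_contour(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        gmean, gmax, count = om.groove_depths(c)
        assert gmax == pytest.approx(0.3, rel=0.05)

    def test_gear_matches_dense_pocket_oracle(self):
        fx = make_grooved_disc(1.0, 0.1, 8)
        c = _poly_contour(fx.boundary_cm)
        _, gmax, _ = om.groove_depths(c)
        dense = om.smooth_resample(c, 0.0, 100_000)
        _, gmax_dense, _ = om.groove_depths(dense)
        assert gmax == pytest.approx(gmax_dense, rel=0.02)

    def test_rotation_invariant(self):
        fx = make_grooved_disc(1.0, 0.1, 8)
        c = _poly_contour(fx.boundary_cm)
        base = om.groove_depths(c)
        rng = np.random.default_rng(5)
        for phi in rng.uniform(0, 2 * np.pi, 3):
            rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            rc = Contour(c.vertices @ rot.T, calibrated=True)
            got = om.groove_depths(rc)
            assert got[0] == pytest.approx(base[0], rel=0.005)
            assert got[1] == pytest.approx(base[1], rel=0.005)


class TestEndocarpProfile:
    def test_circle_all_views(self):
        c = circle_contour(1.0)
        t = om.endocarp_profile(c, c, c)
        blk = t.c_block
        assert blk["StArConv"] == pytest.approx(1.0, abs=1e-4)
        assert blk["GrooveMeanDepth"] == 0.0 and blk["GrooveMaxDepth"] == 0.0
        assert blk["DiamInscrCir"] == pytest.approx(blk["DiamMinBdCir"], rel=0.01)

    def test_grooved_disc_convexity_matches_truth(self):
        fx = make_grooved_disc(1.0, 0.1, 8)
        c = measure_fixture(fx, orient=False)
        t = om.endocarp_profile(None, None, c)
        assert t.c_block["StArConv"] == pytest.approx(fx.truth["st_ar_conv"], rel=0.01)
        assert not t.a_present and not t.b_present
        assert np.isnan(t.as_row()["ShIdx-A"])

    def test_rougher_is_less_convex(self):
        vals = []
        for amp in (0.02, 0.06, 0.12):
            fx = make_grooved_disc(1.0, amp, 8)
            vals.append(om.area_convexity(_poly_contour(fx.boundary_cm)))
        assert vals[0] > vals[1] > vals[2]

    def test_centroid_within_bounding_circle(self):
        fx = make_grooved_disc(1.0, 0.1, 8)
        c = _poly_contour(fx.boundary_cm)
        _, max_cent = om.centre_distances(c)
        assert max_cent <= om.bounding_circle_diameter(c)

    def test_block_counts(self):
        c = circle_contour(1.0)
        row = om.endocarp_profile(c, c, c).as_row()
        assert sum(k.endswith("-A") for k in row) == 11
        assert sum(k.endswith("-B") for k in row) == 11
        assert sum(k.endswith("-C") for k in row) == 22
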