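"""Geometry core: PCA solver, plane projection, pixelation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ivims.geometry import (
    DetectorPlane,
    Line3,
    Point3,
    make_stack,
    pca_batch,
    pixel_center,
    pixelate,
    point_of_closest_approach,
    project_to_plane,
)


def brute_force_pca(l1: Line3, l2: Line3) -> tuple[np.ndarray, float]:
    """Independent oracle: numeric 2D minimization over both line parameters.

    Minimizes the squared distance between points on the two lines; the PCA
    point is the midpoint of the minimizing segment and the per-line miss
    distance is half the segment length.
    """

    def cost(st_):
        s, t = st_
        return float(np.sum((l1.point_at(s) - l2.point_at(t)) ** 2))

    def grad(st_):
        s, t = st_
        w = l1.point_at(s) - l2.point_at(t)
        return np.array([2 * w @ l1.d, -2 * w @ l2.d])

    res = minimize(cost, x0=[0.0, 0.0], method="BFGS", jac=grad, options={"gtol": 1e-12})
    # one exact Newton step on the quadratic cost to polish ill-conditioned
    # (near-parallel) valleys; Hessian is constant: 2 [[1, -c], [-c, 1]]
    c = float(l1.d @ l2.d)
    hess = 2.0 * np.array([[1.0, -c], [-c, 1.0]])
    x = res.x - np.linalg.solve(hess, grad(res.x))
    p1, p2 = l1.point_at(x[0]), l2.point_at(x[1])
    return 0.5 * (p1 + p2), 0.5 * float(np.linalg.norm(p1 - p2))


class TestPointOfClosestApproach:
    def test_intersecting_lines_meet_at_intersection(self):
        frag = Line3.through((0, 0, 0), (1, 0, 0))
        beam = Line3.through((0, 0, 0), (0, 1, 0))
        v, status = point_of_closest_approach(frag, beam)
        assert status == "ok"
        np.testing.assert_allclose(v.position.array, [0, 0, 0], atol=1e-12)
        assert v.miss_distance == pytest.approx(0.0, abs=1e-12)

    def test_parallel_lines_flagged_degenerate(self):
        frag = Line3.through((0, 0, 0), (1, 0, 0))
        beam = Line3.through((0, 10, 0), (1, 0, 0))
        v, status = point_of_closest_approach(frag, beam)
        assert status == "degenerate"
        assert v is None

    def test_skew_lines_match_numeric_minimization(self):
        # frag along x, beam through (0,10,10) along y: expect (0,0,5), miss 5
        frag = Line3.through((0, 0, 0), (1, 0, 0))
        beam = Line3.through((0, 10, 10), (0, 1, 0))
        v, status = point_of_closest_approach(frag, beam)
        assert status == "ok"
        p_oracle, miss_oracle = brute_force_pca(frag, beam)
        np.testing.assert_allclose(v.position.array, p_oracle, atol=1e-6)
        np.testing.assert_allclose(v.position.array, [0, 0, 5], atol=1e-9)
        assert v.miss_distance == pytest.approx(5.0, abs=1e-9)
        assert miss_oracle == pytest.approx(5.0, abs=1e-6)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            Line3.through((0, 0, 0), (0, 0, 0))

    def test_equals_brute_force_on_random_skew_pairs(self):
        """Solver == brute-force numeric minimization on 1000 random pairs."""
        rng = np.random.default_rng(7)
        n_checked = 0
        while n_checked < 1000:
            a1, a2 = rng.normal(0, 50, 3), rng.normal(0, 50, 3)
            d1, d2 = rng.normal(size=3), rng.normal(size=3)
            if np.linalg.norm(d1) < 1e-3 or np.linalg.norm(d2) < 1e-3:
                continue
            l1, l2 = Line3.through(a1, d1), Line3.through(a2, d2)
            if abs(l1.d @ l2.d) > 1 - 1e-6:
                continue
            v, status = point_of_closest_approach(l1, l2)
            assert status == "ok"
            p_oracle, _ = brute_force_pca(l1, l2)
            assert np.linalg.norm(v.position.array - p_oracle) <= 1e-6
            n_checked += 1

    @given(st.integers(0, 10_000))
    def test_symmetric_and_rigid_equivariant(self, case):
        rng = np.random.default_rng(case)
        l1 = Line3.through(rng.normal(0, 20, 3), rng.normal(size=3))
        l2 = Line3.through(rng.normal(0, 20, 3), rng.normal(size=3))
        if abs(l1.d @ l2.d) > 1 - 1e-4:
            return
        v12, _ = point_of_closest_approach(l1, l2)
        v21, _ = point_of_closest_approach(l2, l1)
        np.testing.assert_allclose(v12.position.array, v21.position.array, atol=1e-9)

        rot = Rotation.random(random_state=case).as_matrix()
        shift = rng.normal(0, 30, 3)
        t1 = Line3.through(rot @ l1.a + shift, rot @ l1.d)
        t2 = Line3.through(rot @ l2.a + shift, rot @ l2.d)
        vt, _ = point_of_closest_approach(t1, t2)
        np.testing.assert_allclose(vt.position.array, rot @ v12.position.array + shift, atol=1e-9)

    def test_batch_matches_scalar(self, rng):
        n = 200
        a1 = rng.normal(0, 30, (n, 3))
        a2 = rng.normal(0, 30, (n, 3))
        d1 = rng.normal(size=(n, 3))
        d2 = rng.normal(size=(n, 3))
        d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
        d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
        pts, miss, ok = pca_batch(a1, d1, a2, d2)
        for i in range(n):
            v, status = point_of_closest_approach(
                Line3.through(a1[i], d1[i]), Line3.through(a2[i], d2[i])
            )
            if status == "ok":
                assert ok[i]
                np.testing.assert_allclose(pts[i], v.position.array, atol=1e-9)
                assert miss[i] == pytest.approx(v.miss_distance, abs=1e-9)
            else:
                assert not ok[i]


class TestPlaneProjection:
    def test_axial_line_through_center(self, default_stack):
        plane = default_stack.front
        line = Line3.through((0, 0, 0), plane.normal)
        u, v, hit = project_to_plane(line, plane)
        assert hit
        assert u == pytest.approx(0.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_off_area_misses(self, default_stack):
        plane = default_stack.front
        # aim 30 mm off-center along the in-plane u axis of a 25 mm half-width
        target = plane.center.array + 30.0 * np.asarray(plane.axis_u)
        line = Line3.through((0, 0, 0), target)
        u, v, hit = project_to_plane(line, plane)
        assert not hit
        assert abs(u) > plane.half_width

    def test_oblique_line_matches_vector_algebra(self):
        # plane z=100 with identity axes; line from origin with slope
        plane = DetectorPlane(
            center=Point3(0, 0, 100),
            normal=(0, 0, 1),
            axis_u=(1, 0, 0),
            axis_v=(0, 1, 0),
        )
        line = Line3.through((1.0, -2.0, 0.0), (0.1, 0.2, 1.0))
        u, v, hit = project_to_plane(line, plane)
        # independent algebra: t = 100 / dz; p = a + t d
        d = np.array([0.1, 0.2, 1.0]) / np.linalg.norm([0.1, 0.2, 1.0])
        t = 100.0 / d[2]
        p = np.array([1.0, -2.0, 0.0]) + t * d
        assert u == pytest.approx(p[0], abs=1e-9)
        assert v == pytest.approx(p[1], abs=1e-9)
        assert hit

    def test_parallel_line_raises(self, default_stack):
        plane = default_stack.front
        line = Line3.through((0, 0, 0), plane.axis_u)
        with pytest.raises(ValueError, match="parallel"):
            project_to_plane(line, plane)


class TestPixelate:
    def test_quantization_bound_at_origin(self, default_stack):
        plane = default_stack.front
        iu, iv, uc, vc = pixelate(0.0, 0.0, plane)
        assert abs(uc - 0.0) <= plane.pixel_pitch / 2
        assert abs(vc - 0.0) <= plane.pixel_pitch / 2

    def test_lower_edge_is_index_zero(self, default_stack):
        plane = default_stack.front
        iu, iv, *_ = pixelate(-plane.half_width, -plane.half_height, plane)
        assert iu == 0 and iv == 0

    def test_out_of_area_raises(self, default_stack):
        with pytest.raises(ValueError):
            pixelate(30.0, 0.0, default_stack.front)

    @given(st.floats(-24.999, 24.999), st.floats(-24.999, 24.999))
    def test_pixelate_of_center_is_idempotent(self, u, v):
        plane = make_stack().front
        iu, iv, uc, vc = pixelate(u, v, plane)
        iu2, iv2, uc2, vc2 = pixelate(uc, vc, plane)
        assert (iu2, iv2) == (iu, iv)
        assert (uc2, vc2) == (uc, vc)
        # in-plane quantization error never exceeds pitch/sqrt(2)
        assert np.hypot(uc - u, vc - v) <= plane.pixel_pitch / np.sqrt(2) + 1e-12

    def test_center_roundtrip_exact(self, default_stack):
        plane = default_stack.front
        iu = np.arange(0, plane.n_u, 37)
        iv = np.arange(0, plane.n_v, 37)[: len(iu)]
        uc, vc = pixel_center(iu, iv[: len(iu)], plane)
        ju, jv, *_ = pixelate(uc, vc, plane)
        np.testing.assert_array_equal(ju, iu)
        np.testing.assert_array_equal(jv, iv[: len(iu)])


class TestStackGeometry:
    def test_back_plane_is_translated_front(self, default_stack):
        st_ = default_stack
        np.testing.assert_allclose(
            st_.back.center.array,
            st_.front.center.array + st_.plane_spacing * np.asarray(st_.front.normal),
            atol=1e-9,
        )

    def test_angle_and_distance(self, default_stack):
        c = default_stack.front.center.array
        assert np.linalg.norm(c) == pytest.approx(140.0)
        cos_angle = c[2] / np.linalg.norm(c)
        assert np.degrees(np.arccos(cos_angle)) == pytest.approx(30.0)

    def test_mismatched_back_plane_rejected(self, default_stack):
        from ivims.geometry import StackGeometry

        with pytest.raises(ValueError):
            StackGeometry(
                front=default_stack.front,
                back=default_stack.front,
                plane_spacing=50.0,
            )
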