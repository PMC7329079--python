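"""Null-space construction, chord extents and ellipsoidal rounding."""

import numpy as np
import pytest

import fluxpolytope as fp
from fluxpolytope.polytope import (
    chebyshev_center,
    chord_extent,
    max_volume_ellipsoid,
    nullspace_basis,
    round_polytope,
    sandwiching_ratio_estimate,
)

from conftest import rotated_box_polytope


class TestNullspaceBasis:
    def test_two_flux_line(self):
        G = nullspace_basis(np.array([[1.0, -1.0]]))
        assert G.shape == (2, 1)
        np.testing.assert_allclose(np.abs(G[:, 0]), 1 / np.sqrt(2), atol=1e-12)

    def test_zero_matrix_full_space(self):
        G = nullspace_basis(np.zeros((1, 2)))
        assert G.shape == (2, 2)
        np.testing.assert_allclose(G.T @ G, np.eye(2), atol=1e-12)

    def test_random_rank5_residual(self):
        rng = np.random.default_rng(11)
        S = rng.standard_normal((5, 8))
        G = nullspace_basis(S)
        assert G.shape == (8, 3)
        assert np.max(np.abs(S @ G)) < 1e-10
        np.testing.assert_allclose(G.T @ G, np.eye(3), atol=1e-12)

    def test_trivial_nullspace_raises(self):
        with pytest.raises(ValueError, match="point"):
            nullspace_basis(np.eye(3))


class TestBuildPolytope:
    def test_two_flux_segment_length(self, two_flux_poly):
        # feasible segment runs from (0,0) to (10,10): length 10*sqrt(2) in u
        lo, hi = chord_extent(two_flux_poly, two_flux_poly.anchor, np.array([1.0]))
        assert (hi - lo) == pytest.approx(10 * np.sqrt(2), rel=1e-9)

    def test_anchor_strictly_interior(self, random_model):
        model, _ = random_model
        poly = fp.build_polytope(model)
        assert np.all(poly.slack(poly.anchor) > 1e-9)
        assert poly.dim == model.n - np.linalg.matrix_rank(model.S)

    def test_fixed_flux_pins_interior(self):
        # v1 fixed at 2 and v1=v2 pin u exactly: the polytope is a point,
        # which has no interior in u-space
        model = fp.synthetic_data.make_two_flux_model(lb=(2.0, 0.0), ub=(2.0, 10.0))
        with pytest.raises(ValueError, match="interior"):
            fp.build_polytope(model)

    def test_infeasible_bounds_raise(self):
        model = fp.synthetic_data.make_two_flux_model(lb=(5.0, 0.0), ub=(10.0, 4.0))
        with pytest.raises(ValueError):
            fp.build_polytope(model)


class TestChordExtent:
    def test_unit_box_center_axis(self, unit_box_2d):
        poly, _ = unit_box_2d
        lo, hi = chord_extent(poly, np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert lo == pytest.approx(-0.5)
        assert hi == pytest.approx(0.5)

    def test_near_face_point(self, unit_box_2d):
        poly, _ = unit_box_2d
        eps = 1e-9
        lo, hi = chord_extent(poly, np.array([1.0 - eps, 0.5]), np.array([1.0, 0.0]))
        assert hi == pytest.approx(eps, abs=1e-12)

    def test_brute_force_scan_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((12, 3))
        b = A @ np.zeros(3) + rng.uniform(0.5, 2.0, 12)  # origin interior
        poly = fp.FluxPolytope(
            G=np.eye(3), A_ineq=A, b_ineq=b, anchor=np.zeros(3), reaction_ids=list("abc")
        )
        for _ in range(10):
            theta = rng.standard_normal(3)
            theta /= np.linalg.norm(theta)
            lo, hi = chord_extent(poly, np.zeros(3), theta)
            lam_grid = np.linspace(lo - 0.2, hi + 0.2, 4001)
            feas = np.array([poly.contains(lam * theta, tol=1e-12) for lam in lam_grid])
            inside = lam_grid[feas]
            assert inside.min() >= lo - 1e-3 and inside.max() <= hi + 1e-3
            assert poly.contains(lo * theta, tol=1e-9)
            assert poly.contains(hi * theta, tol=1e-9)

    def test_infeasible_origin_raises(self, unit_box_2d):
        poly, _ = unit_box_2d
        with pytest.raises(ValueError, match="outside"):
            chord_extent(poly, np.array([2.0, 0.5]), np.array([1.0, 0.0]))

    def test_zero_direction_raises(self, unit_box_2d):
        poly, _ = unit_box_2d
        with pytest.raises(ValueError, match="zero direction"):
            chord_extent(poly, np.array([0.5, 0.5]), np.zeros(2))


class TestMaxVolumeEllipsoid:
    def test_axis_box_analytic(self):
        poly, _ = fp.synthetic_data.make_box_polytope([1.0, 100.0])
        c, B = max_volume_ellipsoid(poly.A_ineq, poly.b_ineq)
        np.testing.assert_allclose(c, [0.5, 50.0], atol=1e-6)
        np.testing.assert_allclose(np.sort(np.linalg.svd(B, compute_uv=False)), [0.5, 50.0], atol=1e-6)

    def test_rotated_box_analytic(self):
        # the exact-box shortcut does not apply; the solver must find the
        # rotated analytic MVE (semi-axes = half sides)
        poly, R = rotated_box_polytope([2.0, 6.0], angle_deg=30.0)
        c, B = max_volume_ellipsoid(poly.A_ineq, poly.b_ineq)
        semi = np.sort(np.linalg.svd(B, compute_uv=False))
        np.testing.assert_allclose(semi, [1.0, 3.0], rtol=1e-4)
        np.testing.assert_allclose(R @ c, [1.0, 3.0], atol=1e-4)

    def test_regular_polygon_near_identity(self):
        # 16-gon approximating the unit disk: MVE close to the unit ball
        k = np.arange(16)
        A = np.column_stack([np.cos(2 * np.pi * k / 16), np.sin(2 * np.pi * k / 16)])
        b = np.ones(16)
        c, B = max_volume_ellipsoid(A, b)
        np.testing.assert_allclose(c, 0.0, atol=1e-5)
        s = np.linalg.svd(B, compute_uv=False)
        assert s.max() / s.min() < 1.01

    def test_mve_volume_below_polytope_volume(self):
        # Monte-Carlo volume oracle on a 2-D triangle
        A = np.array([[-1.0, 0.0], [0.0, -1.0], [1.0, 1.0]])
        b = np.array([0.0, 0.0, 1.0])
        c, B = max_volume_ellipsoid(A, b)
        vol_mve = np.pi * np.prod(np.linalg.svd(B, compute_uv=False))
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, size=(200_000, 2))
        vol_tri = np.mean(np.all(A @ pts.T <= b[:, None], axis=0))  # fraction of unit square
        assert vol_mve < vol_tri
        assert vol_mve > 0.5 * vol_tri  # MVE of a simplex is not tiny


class TestRounding:
    def test_rounding_improves_aspect(self):
        poly, R = rotated_box_polytope([1.0, 1e4], angle_deg=30.0)
        rounded, transform = round_polytope(poly)
        c, B = max_volume_ellipsoid(rounded.A_ineq, rounded.b_ineq)
        s = np.linalg.svd(B, compute_uv=False)
        assert s.max() / s.min() < 10.0
        assert sandwiching_ratio_estimate(transform.T) > 1e3  # input was that skewed

    def test_round_trip_identity(self):
        poly, _ = rotated_box_polytope([1.0, 50.0])
        _, transform = round_polytope(poly)
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 2))
        np.testing.assert_allclose(transform.to_rounded(transform.to_original(y)), y, atol=1e-9)

    def test_samples_map_back_feasible(self):
        poly, _ = rotated_box_polytope([1.0, 1e3])
        rounded, transform = round_polytope(poly)
        chain = fp.hr_sample(rounded, M=500, thinning=1, seed=9, direction_mode="coordinate")
        U = transform.to_original(chain.extra["u_samples"])
        slack = poly.b_ineq[None, :] - U @ poly.A_ineq.T
        assert slack.min() > -1e-8

    def test_unbounded_polytope_raises(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])  # no lower bounds: unbounded
        b = np.ones(2)
        with pytest.raises(ValueError):
            max_volume_ellipsoid(A, b)


def test_polytope_serialization_roundtrip(tmp_path, two_flux_poly):
    path = tmp_path / "poly.npz"
    two_flux_poly.save(path)
    back = fp.FluxPolytope.load(path)
    np.testing.assert_array_equal(back.G, two_flux_poly.G)
    np.testing.assert_array_equal(back.b_ineq, two_flux_poly.b_ineq)
    assert back.reaction_ids == two_flux_poly.reaction_ids
    assert back.contains(back.anchor)


def test_box_sandwiching_ground_truth():
    poly, truth = fp.synthetic_data.make_box_polytope([1.0, 1e4])
    c, B = max_volume_ellipsoid(poly.A_ineq, poly.b_ineq)
    est = sandwiching_ratio_estimate(B)
    assert est == pytest.approx(truth.extras["sandwiching_ratio"], rel=1e-6)
    assert est == pytest.approx(1e4, rel=1e-3)
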