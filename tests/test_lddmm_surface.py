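"""Currents metric, kernel flows, log-Jacobians, and surface matching."""

import numpy as np
import pytest

from tractsurf.lddmm_surface import (
    AffineMap, Diffeomorphism, KernelSpec, MatchOptions, _objective_and_grad,
    currents_energy, currents_inner, flow_points, gaussian_kernel,
    integrate_flow, jacobian_logdet, match_surfaces,
)
from tractsurf.mesh_core import TriMesh, compute_current, icosphere


@pytest.fixture(scope="module")
def sphere():
    return icosphere(radius=5.0, subdivisions=1, center=(1.0, -2.0, 0.5))


def _zero_flow(points, n_steps=5):
    q = np.asarray(points, dtype=np.float64)
    traj = np.repeat(q[None], n_steps + 1, axis=0)
    return Diffeomorphism(traj, np.zeros((n_steps,) + q.shape), 10.0, n_steps)


class TestGaussianKernel:
    def test_diagonal_is_one(self):
        pts = np.random.default_rng(0).normal(size=(7, 3))
        K = gaussian_kernel(pts, pts, sigma=3.0)
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)

    def test_matches_scalar_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        K = gaussian_kernel(a, b, sigma=2.5)
        for i in range(4):
            for j in range(5):
                d2 = np.sum((a[i] - b[j]) ** 2)
                assert K[i, j] == pytest.approx(np.exp(-d2 / 2.5 ** 2), abs=1e-12)


class TestCurrents:
    def test_self_energy_zero(self, sphere):
        cur = compute_current(sphere)
        assert currents_energy(cur, cur, sigma_w=5.0) == pytest.approx(0.0, abs=1e-9)

    def test_inner_product_brute_force_oracle(self, sphere):
        other = icosphere(radius=4.0, subdivisions=1, center=(3.0, 0.0, -1.0))
        a, b = compute_current(sphere), compute_current(other)
        sigma = 4.0
        brute = 0.0
        for f in range(len(a.centers)):
            for g in range(len(b.centers)):
                d2 = np.sum((a.centers[f] - b.centers[g]) ** 2)
                brute += np.exp(-d2 / sigma ** 2) * float(a.normals[f] @ b.normals[g])
        assert currents_inner(a, b, sigma) == pytest.approx(brute, rel=1e-10)

    def test_energy_symmetric_and_nonnegative(self, sphere):
        other = icosphere(radius=5.5, subdivisions=1, center=(0.0, 0.0, 0.0))
        a, b = compute_current(sphere), compute_current(other)
        e_ab = currents_energy(a, b, sigma_w=5.0)
        e_ba = currents_energy(b, a, sigma_w=5.0)
        assert e_ab == pytest.approx(e_ba, rel=1e-10)
        assert e_ab > 0

    def test_orientation_flip_changes_energy(self, sphere):
        a = compute_current(sphere)
        flipped = compute_current(sphere.flipped())
        # a closed surface and its inward-oriented copy are far apart as currents
        assert currents_energy(a, flipped, sigma_w=5.0) > 1.0


class TestFlow:
    def test_zero_momenta_is_identity(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 3)) * 5
        flow = _zero_flow(rng.normal(size=(6, 3)))
        np.testing.assert_allclose(flow_points(flow, pts), pts, atol=1e-14)

    def test_forward_then_inverse_near_identity(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(-5, 5, (10, 3))
        flow = integrate_flow(q, rng.normal(0, 0.5, (10, 3)), sigma_v=8.0, n_steps=10)
        pts = rng.uniform(-4, 4, (30, 3))
        back = flow_points(flow, flow_points(flow, pts), inverse=True)
        # the time-reversed integrator is an O(dt) inverse
        assert np.max(np.linalg.norm(back - pts, axis=1)) < 0.15

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        flow = integrate_flow(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)),
                              sigma_v=6.0, n_steps=10)
        flow.save(tmp_path / "flow.npz")
        back = Diffeomorphism.load(tmp_path / "flow.npz")
        pts = rng.normal(size=(8, 3))
        np.testing.assert_array_equal(flow_points(back, pts), flow_points(flow, pts))

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="n_steps"):
            Diffeomorphism(np.zeros((3, 4, 3)), np.zeros((3, 4, 3)), 5.0, 3)


class TestJacobianLogdet:
    def test_identity_map_gives_zero(self):
        pts = np.random.default_rng(5).normal(size=(12, 3))
        lj = jacobian_logdet(_zero_flow(np.zeros((4, 3))), pts)
        np.testing.assert_allclose(lj, 0.0, atol=1e-10)

    @pytest.mark.parametrize("s", [0.8, 0.9, 1.25])
    def test_uniform_scaling_gives_3_log_s(self, s):
        amap = AffineMap(matrix=s * np.eye(3))
        pts = np.random.default_rng(6).normal(size=(15, 3)) * 10
        lj = jacobian_logdet(amap, pts)
        np.testing.assert_allclose(lj, 3.0 * np.log(s), atol=1e-9)

    def test_general_affine_matches_closed_form(self):
        rng = np.random.default_rng(7)
        A = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        amap = AffineMap(matrix=A, translation=rng.normal(size=3))
        lj = jacobian_logdet(amap, rng.normal(size=(9, 3)))
        np.testing.assert_allclose(lj, np.log(np.linalg.det(A)), atol=1e-8)

    def test_orientation_reversing_map_raises(self):
        amap = AffineMap(matrix=np.diag([-1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="orientation"):
            jacobian_logdet(amap, np.zeros((1, 3)))


class TestObjectiveGradient:
    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(8)
        src = icosphere(radius=4.0, subdivisions=0)
        dst = icosphere(radius=4.5, subdivisions=0, center=(0.8, 0.0, 0.0))
        target = compute_current(dst)
        q0 = src.vertices.copy()
        alpha = rng.normal(0, 0.1, q0.shape)
        args = (q0, src.vertices, src.faces, target, 6.0, 4.0, 1.0, 5)
        f0, g, _, _ = _objective_and_grad(alpha, *args)
        eps = 1e-5
        idx = [(0, 0), (3, 1), (7, 2), (10, 0)]
        for i, k in idx:
            da = alpha.copy(); da[i, k] += eps
            db = alpha.copy(); db[i, k] -= eps
            fd = (_objective_and_grad(da, *args)[0]
                  - _objective_and_grad(db, *args)[0]) / (2 * eps)
            assert g[i, k] == pytest.approx(fd, rel=2e-4, abs=1e-8)


class TestMatchSurfaces:
    def test_self_match_keeps_identity(self, sphere):
        res = match_surfaces(sphere, sphere, KernelSpec(8.0, 5.0), 1.0,
                             MatchOptions(max_iter=10))
        assert res.data_term == pytest.approx(0.0, abs=1e-8)
        moved = flow_points(res.diffeo, sphere.vertices)
        assert np.max(np.linalg.norm(moved - sphere.vertices, axis=1)) < 1e-6

    def test_translation_recovered(self, sphere):
        shift = np.array([2.0, -1.0, 0.5])
        target = sphere.with_vertices(sphere.vertices + shift)
        res = match_surfaces(sphere, target, KernelSpec(10.0, 5.0), 4.0,
                             MatchOptions(max_iter=80, rel_tol=1e-8))
        moved = flow_points(res.diffeo, sphere.vertices)
        err = np.linalg.norm(moved - target.vertices, axis=1)
        assert np.mean(err) < 0.35

    def test_energy_trace_monotone_nonincreasing(self, sphere):
        target = sphere.with_vertices(sphere.vertices * 1.15)
        res = match_surfaces(sphere, target, KernelSpec(8.0, 5.0), 1.0,
                             MatchOptions(max_iter=30))
        trace = res.energy_trace
        assert np.all(np.diff(trace) <= 1e-10)

    def test_expansion_gives_positive_logjac(self, sphere):
        target = sphere.with_vertices(
            sphere.vertices * 1.2 - 0.2 * sphere.vertices.mean(axis=0))
        res = match_surfaces(sphere, target, KernelSpec(10.0, 5.0), 4.0,
                             MatchOptions(max_iter=80, rel_tol=1e-8))
        lj = jacobian_logdet(res.diffeo, sphere.vertices)
        assert np.mean(lj) > 0.2

    def test_control_point_subsampling(self, sphere):
        target = sphere.with_vertices(sphere.vertices + [1.0, 0.0, 0.0])
        res = match_surfaces(sphere, target, KernelSpec(10.0, 5.0), 2.0,
                             MatchOptions(max_iter=30, max_control_points=12))
        assert res.diffeo.control_trajectory.shape[1] == 12
        moved = flow_points(res.diffeo, sphere.vertices)
        assert np.mean(np.linalg.norm(moved - target.vertices, axis=1)) < 0.5
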