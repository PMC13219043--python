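import numpy as np
import pytest

from probereg import (ADMMState, DegenerateGeometryError, LostRegistrationError,
                      ParameterError, PointCloud, RigidTransform, SparseICPParams,
                      admm_inner_loop, apply_transform, build_linear_system,
                      build_spatial_index, compose, find_correspondences,
                      icp_point_to_plane, icp_point_to_point, invert, kabsch_align,
                      objective_value, prox_lp, sparse_icp_register)
from probereg.evaluation import evaluate_registration
from probereg.phantom import PhantomConfig, make_phantom, perturb_transform
from probereg.surface import CorrespondenceSet


# ---------------------------------------------------------------------------
# proximal operator
# ---------------------------------------------------------------------------

def prox_grid_oracle(e, mu, p, resolution=1e-6):
    """Two-stage 1-D grid search for argmin |z|^p + (mu/2)(z-e)^2."""
    def f(z):
        return np.abs(z) ** p + 0.5 * mu * (z - e) ** 2
    span = abs(e) + 1.0
    z = np.linspace(-span, span, 40001)  # coarse pass, 5e-5*span spacing
    z0 = z[np.argmin(f(z))]
    w = span * 1e-4
    z = np.linspace(z0 - w, z0 + w, int(2 * w / resolution) + 1)
    zf = z[np.argmin(f(z))]
    return 0.0 if f(0.0) <= f(zf) else zf


class TestProxLp:
    def test_zero_input_gives_zero(self):
        assert prox_lp(0.0, 1.0, 0.5) == 0.0

    def test_threshold_region_hand_case(self):
        # p=0.5, mu=1: |e|=0.5 is deep inside the dead zone
        assert prox_lp(0.5, 1.0, 0.5) == 0.0
        assert prox_grid_oracle(0.5, 1.0, 0.5) == 0.0

    def test_large_input_shrinks_slightly(self):
        z = prox_lp(10.0, 1.0, 0.5)
        assert 9.0 < z < 10.0
        assert abs(z - prox_grid_oracle(10.0, 1.0, 0.5)) < 1e-5

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.8])
    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0])
    def test_matches_grid_oracle(self, p, mu):
        for e in np.linspace(-6.0, 6.0, 25):
            z = prox_lp(e, mu, p)
            assert abs(z - prox_grid_oracle(e, mu, p)) < 1e-5, (e, mu, p)

    def test_sign_and_magnitude_invariants(self, rng):
        e = rng.uniform(-20, 20, 200)
        z = prox_lp(e, 1.0, 0.5)
        assert np.all(np.abs(z) <= np.abs(e) + 1e-12)
        nz = z != 0
        assert np.all(np.sign(z[nz]) == np.sign(e[nz]))

    def test_dead_zone_contiguous_and_symmetric(self):
        e = np.linspace(-5, 5, 2001)
        z = prox_lp(e, 1.0, 0.5)
        dead = np.flatnonzero(z == 0)
        assert np.array_equal(dead, np.arange(dead[0], dead[-1] + 1))
        np.testing.assert_array_equal(z == 0, (z == 0)[::-1])

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            prox_lp(1.0, 1.0, 1.5)
        with pytest.raises(ParameterError):
            prox_lp(1.0, -1.0, 0.5)


# ---------------------------------------------------------------------------
# objective / linearization / solve
# ---------------------------------------------------------------------------

def make_corrs(x, y, n):
    x, y, n = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (x, y, n))
    m = x.shape[0]
    return CorrespondenceSet(
        source_points=x, target_points=y, target_normals=n,
        distances=np.linalg.norm(x - y, axis=1), kept=np.ones(m, dtype=bool),
        source_indices=np.arange(m), target_indices=np.arange(m))


class TestObjective:
    def test_zero_on_surface(self):
        corrs = make_corrs([[1, 0, 0]], [[1, 0, 0]], [[0, 0, 1]])
        assert objective_value(corrs, RigidTransform.identity(), 0.5) == 0.0

    def test_single_pair_hand_value(self):
        # residual 4 mm against the plane, p = 0.5 -> 4^0.5 = 2
        corrs = make_corrs([[0, 0, 4.0]], [[0, 0, 0.0]], [[0, 0, 1.0]])
        assert abs(objective_value(corrs, RigidTransform.identity(), 0.5) - 2.0) < 1e-12

    def test_matches_direct_summation(self, rng):
        m = 20
        x, y = rng.normal(size=(m, 3)), rng.normal(size=(m, 3))
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        corrs = make_corrs(x, y, n)
        expected = np.sum(np.abs(np.einsum("ij,ij->i", n, x - y)) ** 0.5)
        assert abs(objective_value(corrs, RigidTransform.identity(), 0.5)
                   - expected) < 1e-12


class TestLinearizedSystem:
    def test_hand_row(self):
        # x=(1,0,0), n=(0,0,1): x cross n = (0,-1,0), so A=[0,-1,0,0,0,1]; the
        # residual n.(x-y) is zero for y=(0,0,0), hence b = z = 0
        corrs = make_corrs([[1.0, 0, 0]], [[0.0, 0, 0]], [[0.0, 0, 1.0]])
        system = build_linear_system(corrs, np.zeros(1))
        np.testing.assert_allclose(system.A[0], [0, -1, 0, 0, 0, 1], atol=1e-15)
        assert system.b[0] == 0.0

    def test_predicts_post_increment_residual(self, rng):
        m = 40
        # bounded support: the second-order linearization error scales with |x|
        x = rng.uniform(-1, 1, size=(m, 3))
        x *= 10.0 / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1.0)
        y = x + rng.normal(size=(m, 3)) * 0.5
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        corrs = make_corrs(x, y, n)
        system = build_linear_system(corrs, np.zeros(m))
        xi = rng.normal(size=6)
        xi[:3] *= 1e-3 / np.linalg.norm(xi[:3])
        xi[3:] *= 1e-3
        from probereg import exp_so3
        moved = RigidTransform(exp_so3(xi[:3]), xi[3:])
        true_r = np.einsum("ij,ij->i", n, moved.apply(x) - y)
        predicted = system.A @ xi - system.b
        np.testing.assert_allclose(predicted, true_r, atol=1e-5)

    def test_zero_b_gives_zero_increment(self, rng):
        m = 30
        x = rng.normal(size=(m, 3)) * 10
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        corrs = make_corrs(x, x, n)
        from probereg import solve_increment
        inc = solve_increment(build_linear_system(corrs, np.zeros(m)))
        assert np.linalg.norm(inc.omega) < 1e-12 and np.linalg.norm(inc.dt) < 1e-12

    def test_solve_matches_lstsq_oracle(self, rng):
        from probereg import LinearizedSystem, solve_increment
        A = rng.normal(size=(30, 6))
        b = rng.normal(size=30)
        inc = solve_increment(LinearizedSystem(A=A, b=b), lm_damping=0.0,
                              step_cap=1e9)
        ref, *_ = np.linalg.lstsq(A, b, rcond=None)
        np.testing.assert_allclose(np.concatenate([inc.omega, inc.dt]), ref,
                                   atol=1e-8)

    def test_planar_degeneracy_raises(self, rng):
        # all normals share one direction: only 3 of 6 DOF are constrained
        from probereg import solve_increment
        m = 30
        x = np.column_stack([rng.normal(size=(m, 2)) * 20, np.zeros(m)])
        n = np.tile([0.0, 0.0, 1.0], (m, 1))
        corrs = make_corrs(x, x + rng.normal(size=(m, 3)) * 0.1, n)
        with pytest.raises(DegenerateGeometryError):
            solve_increment(build_linear_system(corrs, np.zeros(m)))


class TestADMMInnerLoop:
    def test_zero_residual_is_fixed_point(self, rng):
        m = 25
        x = rng.normal(size=(m, 3)) * 10
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        corrs = make_corrs(x, x, n)
        params = SparseICPParams()
        pose, state = admm_inner_loop(corrs, ADMMState.zeros(m, params),
                                      RigidTransform.identity(), params)
        assert np.linalg.norm(pose.R - np.eye(3)) < 1e-10
        assert np.linalg.norm(pose.T) < 1e-10
        np.testing.assert_array_equal(state.lam, 0.0)
        np.testing.assert_array_equal(state.z, 0.0)

    def test_lambda_zero_while_constraints_hold(self, rng):
        # delta = n.r - z stays 0 when residuals are 0, so duals never move
        m = 10
        x = rng.normal(size=(m, 3))
        n = rng.normal(size=(m, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        corrs = make_corrs(x, x, n)
        params = SparseICPParams(inner_iters=3)
        _, state = admm_inner_loop(corrs, ADMMState.zeros(m, params),
                                   RigidTransform.identity(), params)
        np.testing.assert_array_equal(state.lam, 0.0)


# ---------------------------------------------------------------------------
# full registration loops
# ---------------------------------------------------------------------------

class TestRegistration:
    def test_ground_truth_init_is_fixed_point(self, clean_phantom, clean_target_normals):
        ph = clean_phantom
        total, trace = sparse_icp_register(ph.probe_cloud, clean_target_normals,
                                           ph.gt_transform, SparseICPParams())
        rep = evaluate_registration(ph, total, pairing="true")
        assert rep.tre < 0.05
        assert trace.termination_reason in ("pose_tol", "obj_tol")
        assert trace.n_iterations <= 20

    def test_recovery_from_coarse_landmarks(self, clean_phantom, clean_target_normals):
        ph = clean_phantom
        sol = kabsch_align(ph.landmarks_patient, ph.landmarks_ct)
        total, trace = sparse_icp_register(ph.probe_cloud, clean_target_normals,
                                           sol.transform, SparseICPParams())
        assert evaluate_registration(ph, total, pairing="true").tre < 0.05

    def test_deterministic_traces(self, clean_phantom, clean_target_normals):
        ph = clean_phantom
        init = perturb_transform(ph.gt_transform, 3.0, 2.0, seed=5)
        a = sparse_icp_register(ph.probe_cloud, clean_target_normals, init)
        b = sparse_icp_register(ph.probe_cloud, clean_target_normals, init)
        assert a[1].objective == b[1].objective
        np.testing.assert_array_equal(a[0].R, b[0].R)
        np.testing.assert_array_equal(a[0].T, b[0].T)

    def test_poses_stay_in_so3(self, clean_phantom, clean_target_normals):
        ph = clean_phantom
        init = perturb_transform(ph.gt_transform, 5.0, 3.0, seed=11)
        total, _ = sparse_icp_register(ph.probe_cloud, clean_target_normals, init)
        R = total.R
        assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-9
        assert abs(np.linalg.det(R) - 1.0) < 1e-9

    def test_lost_registration_raises(self, clean_phantom, clean_target_normals):
        ph = clean_phantom
        far = compose(RigidTransform(np.eye(3), [500.0, 0, 0]), ph.gt_transform)
        with pytest.raises(LostRegistrationError):
            sparse_icp_register(ph.probe_cloud, clean_target_normals, far)

    def test_requires_normals(self, clean_phantom):
        ph = clean_phantom
        with pytest.raises(ValueError, match="normals"):
            sparse_icp_register(ph.probe_cloud, ph.target_cloud, ph.gt_transform)

    def test_point_to_point_converges_and_mse_non_increasing(self, clean_phantom,
                                                             clean_target_normals):
        ph = clean_phantom
        init = perturb_transform(ph.gt_transform, 2.0, 1.0, seed=3)
        total, trace = icp_point_to_point(ph.probe_cloud, clean_target_normals, init)
        assert evaluate_registration(ph, total, pairing="true").tre < 3.0
        mse = np.array(trace.objective)
        assert np.all(np.diff(mse) <= 1e-9)

    def test_point_to_plane_objective_decreases_overall(self, clean_phantom,
                                                        clean_target_normals):
        ph = clean_phantom
        init = perturb_transform(ph.gt_transform, 2.0, 1.0, seed=4)
        total, trace = icp_point_to_plane(ph.probe_cloud, clean_target_normals, init)
        assert trace.objective[-1] < trace.objective[0]
        assert evaluate_registration(ph, total, pairing="true").tre < 0.5

    def test_plane_variants_agree_on_clean_data(self, clean_phantom,
                                                clean_target_normals):
        # without outliers every residual sits far below the Lp dead zone, so
        # the sparse variant reduces to plain point-to-plane
        ph = clean_phantom
        init = perturb_transform(ph.gt_transform, 2.0, 1.0, seed=6)
        t_sparse, _ = sparse_icp_register(ph.probe_cloud, clean_target_normals, init)
        t_plain, _ = icp_point_to_plane(ph.probe_cloud, clean_target_normals, init)
        d_sparse = evaluate_registration(ph, t_sparse, pairing="true").tre
        d_plain = evaluate_registration(ph, t_plain, pairing="true").tre
        assert abs(d_sparse - d_plain) < 0.05

    def test_sparse_beats_plain_under_outliers(self):
        # paired comparison on identical inputs, outlier-contaminated probes
        params = SparseICPParams()
        diffs = []
        for seed in range(6):
            ph = make_phantom(PhantomConfig(seed=seed, probe_noise_sigma=0.2,
                                            outlier_fraction=0.2))
            from probereg import estimate_normals
            tn = estimate_normals(ph.target_cloud, params.k_neighbors)
            init = kabsch_align(ph.landmarks_patient, ph.landmarks_ct).transform
            t_sparse, _ = sparse_icp_register(ph.probe_cloud, tn, init, params)
            t_plain, _ = icp_point_to_plane(ph.probe_cloud, tn, init, params)
            diffs.append(evaluate_registration(ph, t_sparse).tre
                         - evaluate_registration(ph, t_plain).tre)
        assert np.mean(diffs) < 0.0


class TestParams:
    @pytest.mark.parametrize("kw", [dict(p=1.5), dict(p=0.0), dict(mu=0.0),
                                    dict(d_max=-1.0), dict(k_max=0),
                                    dict(inner_iters=0), dict(k_neighbors=2)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ParameterError):
            SparseICPParams(**kw)
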