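import dataclasses
import math

import numpy as np
import pytest
import trimesh

from probereg import (ParameterError, PhantomConfig, apply_transform,
                      make_bone_mesh, make_phantom, perturb_transform,
                      rotation_angle, sample_surface)
from probereg.geometry import compose, invert
from conftest import FAST_DENSE_N


class TestBoneMeshes:
    def test_cup_geometry(self):
        mesh = make_bone_mesh("cup", texture_amp=0.0)
        r = np.linalg.norm(mesh.vertices, axis=1)
        # spherical parts: outer wall at the nominal 27 mm, inner at 21 mm
        outer = r > 26.5
        assert outer.sum() > 1000
        assert np.all(r[outer] <= 27.0 + 1e-9)
        assert np.all((r[outer] >= 26.9) | (r[outer] <= 27.1))
        assert r.min() >= 21.0 - 1e-9
        assert len(mesh.vertices) >= 5000
        assert mesh.is_watertight
        assert mesh.volume > 0

    def test_cup_texture_bounded(self):
        mesh = make_bone_mesh("cup")
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert r.max() <= 27.5 + 1e-9   # nominal radius + relief amplitude

    def test_ball_shaft_geometry(self):
        mesh = make_bone_mesh("ball_shaft", texture_amp=0.0)
        extent = mesh.bounds[1] - mesh.bounds[0]
        # axial length = exposed shaft + head diameter
        assert abs(extent[2] - (80.0 + 46.0)) < 1.0
        assert len(mesh.vertices) >= 5000
        assert mesh.is_watertight
        assert mesh.volume > 0

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ParameterError):
            make_bone_mesh("cup", outer_radius=-1.0)
        with pytest.raises(ParameterError):
            make_bone_mesh("ball_shaft", shaft_radius=30.0)
        with pytest.raises(ParameterError):
            make_bone_mesh("pyramid")


class TestSampleSurface:
    def test_per_triangle_counts_binomial(self):
        square = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False)
        n = 10_000
        cloud = sample_surface(square, n, seed=1)
        # both triangles lie in z=0; recover triangle membership from x+y
        upper = (cloud.points[:, 0] < cloud.points[:, 1]).sum()
        sigma = math.sqrt(n * 0.25)
        assert abs(upper - n / 2) < 3 * sigma

    def test_deterministic_given_seed(self):
        mesh = make_bone_mesh("cup")
        a = sample_surface(mesh, 500, seed=42)
        b = sample_surface(mesh, 500, seed=42)
        np.testing.assert_array_equal(a.points, b.points)

    def test_samples_lie_on_faces(self):
        mesh = make_bone_mesh("cup")
        cloud = sample_surface(mesh, 300, seed=3)
        from trimesh.proximity import closest_point_naive
        _, dist, _ = closest_point_naive(mesh, cloud.points)
        assert np.max(dist) < 1e-9


class TestMakePhantom:
    def test_noise_free_probes_on_surface(self):
        cfg = PhantomConfig(seed=5, dense_n=FAST_DENSE_N, probe_noise_sigma=0.0,
                            landmark_noise_sigma=0.0)
        ph = make_phantom(cfg)
        back = ph.gt_transform.apply(ph.probe_points)
        assert np.max(np.linalg.norm(back - ph.truth_feet, axis=1)) < 1e-6
        from trimesh.proximity import closest_point_naive
        _, dist, _ = closest_point_naive(ph.mesh, back)
        assert np.max(dist) < 1e-6

    def test_fiducials_exact_rigid_pair(self):
        ph = make_phantom(PhantomConfig(seed=2, dense_n=FAST_DENSE_N))
        mapped = ph.gt_transform.apply(ph.fiducials_patient)
        assert np.max(np.abs(mapped - ph.fiducials_ct)) < 1e-9

    def test_outlier_count_and_range(self):
        cfg = PhantomConfig(seed=9, dense_n=FAST_DENSE_N, probe_noise_sigma=0.0,
                            outlier_fraction=0.2, n_probe=30)
        ph = make_phantom(cfg)
        assert len(ph.outlier_indices) == 6
        assert np.all((ph.outlier_offsets >= 2.0) & (ph.outlier_offsets <= 5.0))
        # displaced points sit at their offset from the surface (sigma = 0)
        back = ph.gt_transform.apply(ph.probe_points[ph.outlier_indices])
        d = np.linalg.norm(back - ph.truth_feet[ph.outlier_indices], axis=1)
        np.testing.assert_allclose(d, ph.outlier_offsets, atol=1e-9)

    def test_bit_identical_given_seed(self):
        cfg = PhantomConfig(seed=13, dense_n=FAST_DENSE_N, outlier_fraction=0.1)
        a, b = make_phantom(cfg), make_phantom(cfg)
        np.testing.assert_array_equal(a.probe_points, b.probe_points)
        np.testing.assert_array_equal(a.target_cloud.points, b.target_cloud.points)
        np.testing.assert_array_equal(a.gt_transform.R, b.gt_transform.R)
        np.testing.assert_array_equal(a.landmarks_patient, b.landmarks_patient)
        np.testing.assert_array_equal(a.fiducials_ct, b.fiducials_ct)

    def test_probe_count_change_keeps_ground_truth(self):
        a = make_phantom(PhantomConfig(seed=4, dense_n=FAST_DENSE_N, n_probe=10))
        b = make_phantom(PhantomConfig(seed=4, dense_n=FAST_DENSE_N, n_probe=30))
        np.testing.assert_array_equal(a.gt_transform.R, b.gt_transform.R)
        np.testing.assert_array_equal(a.gt_transform.T, b.gt_transform.T)
        np.testing.assert_array_equal(a.fiducials_ct, b.fiducials_ct)

    def test_probe_points_within_sanity_envelope(self):
        cfg = PhantomConfig(seed=6, dense_n=FAST_DENSE_N, probe_noise_sigma=0.2,
                            outlier_fraction=0.2)
        ph = make_phantom(cfg)
        back = ph.gt_transform.apply(ph.probe_points)
        from trimesh.proximity import closest_point_naive
        _, dist, _ = closest_point_naive(ph.mesh, back)
        assert np.max(dist) <= 0.2 * 4 + 5.0

    def test_landmarks_are_paired_and_on_surface(self):
        ph = make_phantom(PhantomConfig(seed=8, dense_n=FAST_DENSE_N,
                                        landmark_noise_sigma=0.0))
        assert len(ph.landmark_names) >= 3
        mapped = ph.gt_transform.apply(ph.landmarks_patient)
        assert np.max(np.abs(mapped - ph.landmarks_ct)) < 1e-9

    @pytest.mark.parametrize("kw", [dict(n_probe=2), dict(n_fiducials=2),
                                    dict(outlier_fraction=1.0),
                                    dict(probe_noise_sigma=-0.1),
                                    dict(roi_cap_angle=0.5),
                                    dict(shape="cube")])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ParameterError):
            PhantomConfig(**kw)

    def test_ball_shaft_phantom_builds(self):
        ph = make_phantom(PhantomConfig(seed=1, shape="ball_shaft",
                                        dense_n=FAST_DENSE_N,
                                        probe_noise_sigma=0.0,
                                        landmark_noise_sigma=0.0))
        back = ph.gt_transform.apply(ph.probe_points)
        from trimesh.proximity import closest_point_naive
        _, dist, _ = closest_point_naive(ph.mesh, back)
        assert np.max(dist) < 1e-6


class TestPerturbTransform:
    def test_zero_perturbation_returns_gt(self):
        ph = make_phantom(PhantomConfig(seed=3, dense_n=FAST_DENSE_N))
        out = perturb_transform(ph.gt_transform, 0.0, 0.0, seed=1)
        np.testing.assert_allclose(out.R, ph.gt_transform.R, atol=1e-12)
        np.testing.assert_allclose(out.T, ph.gt_transform.T, atol=1e-12)

    def test_exact_rotation_magnitude(self):
        ph = make_phantom(PhantomConfig(seed=3, dense_n=FAST_DENSE_N))
        out = perturb_transform(ph.gt_transform, 5.0, 2.0, seed=1)
        rel = compose(out, invert(ph.gt_transform))
        assert abs(math.degrees(rotation_angle(rel.R)) - 5.0) < 1e-9
        # translation magnitude of the increment is exactly 2 mm
        assert abs(np.linalg.norm(rel.T) - 2.0) < 1e-9

    def test_deterministic(self):
        ph = make_phantom(PhantomConfig(seed=3, dense_n=FAST_DENSE_N))
        a = perturb_transform(ph.gt_transform, 5.0, 2.0, seed=77)
        b = perturb_transform(ph.gt_transform, 5.0, 2.0, seed=77)
        np.testing.assert_array_equal(a.R, b.R)
        np.testing.assert_array_equal(a.T, b.T)
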