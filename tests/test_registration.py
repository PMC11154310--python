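"""Overlap sets, Gauss-Newton camera alignment, objective and baseline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from livestock3d.distance import MeshDistanceQuery
from livestock3d.meshes import TriMesh
from livestock3d.registration import (
    Camera,
    CameraRig,
    RegistrationConfig,
    ResidualMetrics,
    _camera_objective,
    align_camera_to_mesh,
    cem_minimize,
    compute_overlap,
    evaluate_objective,
    residual_metrics,
)
from livestock3d.transforms import RigidTransform, rotation_angle_deg


def make_rig(clouds, poses=None, normals=None):
    cams = []
    for i, pts in enumerate(clouds):
        T = poses[i] if poses else RigidTransform.identity()
        n = normals[i] if normals else np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        cams.append(Camera(cam_id=i, T_init=T, points=pts, normals=n))
    return CameraRig(cams)


def plane_mesh(half=1.0, step=0.1):
    xs = np.arange(-half, half + step / 2, step)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)], axis=1)
    n = len(xs)
    tris = []
    for r in range(n - 1):
        for c in range(n - 1):
            a = r * n + c
            tris.append([a, a + n, a + 1])
            tris.append([a + n, a + n + 1, a + 1])
    return TriMesh(verts, np.array(tris))


class TestComputeOverlap:
    def test_identical_clouds_fully_overlap(self, rng):
        pts = rng.random((50, 3))
        rig = make_rig([pts, pts.copy()])
        ov = compute_overlap(rig, threshold=0.01)
        assert len(ov.indices[0]) == 50 and len(ov.indices[1]) == 50

    def test_distant_clouds_empty_overlap(self, rng):
        pts = rng.random((30, 3)) * 0.1
        with pytest.warns(UserWarning, match="empty overlap"):
            ov = compute_overlap(make_rig([pts, pts + 5.0]), threshold=0.01)
        assert len(ov.indices[0]) == 0 and len(ov.indices[1]) == 0

    def test_interleaved_lattices_match_brute_force(self):
        # oracle: O(n^2) pairwise scan on two offset 1D lattices
        s = 0.02
        a = np.stack([np.arange(20) * s, np.zeros(20), np.zeros(20)], axis=1)
        b = a + [s / 4, 0, 0]
        b = b[::2]
        thr = s / 2
        rig = make_rig([a, b])
        ov = compute_overlap(rig, threshold=thr)
        d_ab = np.linalg.norm(a[:, None] - b[None], axis=2).min(axis=1)
        d_ba = np.linalg.norm(b[:, None] - a[None], axis=2).min(axis=1)
        np.testing.assert_array_equal(ov.indices[0], np.flatnonzero(d_ab <= thr))
        np.testing.assert_array_equal(ov.indices[1], np.flatnonzero(d_ba <= thr))


class TestAlignCameraToMesh:
    def test_already_optimal_stays_put(self, icosphere, rng):
        cfg = RegistrationConfig(kr=0.0, kt=0.0)
        # points exactly on the mesh surface (its own vertices)
        pts = icosphere.vertices[::3]
        T = RigidTransform.identity()
        out = align_camera_to_mesh(pts, T, T, icosphere, cfg)
        assert rotation_angle_deg(out.rotation, np.eye(3)) < 1e-4
        assert np.linalg.norm(out.translation) < 1e-6

    def test_translation_offset_recovered(self, icosphere):
        cfg = RegistrationConfig(kr=0.0, kt=0.0)
        pts = icosphere.vertices[::3]
        T = RigidTransform.from_rotation_translation(np.eye(3), [0.02, 0, 0])
        out = align_camera_to_mesh(pts, T, T, icosphere, cfg)
        assert np.linalg.norm(out.translation) < 1e-3  # back within 1 mm

    def test_huge_regularizer_pins_to_anchor(self, icosphere):
        cfg = RegistrationConfig(kr=1e9, kt=1e9)
        pts = icosphere.vertices[::3]
        T0 = RigidTransform.from_rotation_translation(
            Rotation.from_rotvec([0, 0, 0.01]).as_matrix(), [0.01, 0, 0]
        )
        out = align_camera_to_mesh(pts, T0, T0, icosphere, cfg)
        assert np.abs(out.matrix - T0.matrix).max() < 1e-6

    def test_too_few_correspondences_warns_and_keeps_pose(self, icosphere):
        cfg = RegistrationConfig(kr=0.0, kt=0.0)
        far = np.tile([10.0, 0, 0], (20, 1))  # all beyond the 0.14 cutoff
        T = RigidTransform.identity()
        with pytest.warns(UserWarning, match="fewer than 6"):
            out = align_camera_to_mesh(far, T, T, icosphere, cfg)
        assert out.almost_equal(T)

    def test_objective_never_increases(self, icosphere, rng):
        """Line-search guarantee: the true camera objective is monotone."""
        cfg = RegistrationConfig(kr=0.1, kt=0.1)
        pts = icosphere.vertices[::4] + rng.normal(0, 0.002, (len(icosphere.vertices[::4]), 3))
        T0 = RigidTransform.from_rotation_translation(
            Rotation.from_rotvec([0.01, -0.02, 0.015]).as_matrix(), [0.02, -0.01, 0.03]
        )
        q = MeshDistanceQuery(icosphere)
        e_before = _camera_objective(pts, T0, T0, q, cfg)
        out = align_camera_to_mesh(pts, T0, T0, q, cfg)
        e_after = _camera_objective(pts, out, T0, q, cfg)
        assert e_after <= e_before + 1e-12

    def test_derivative_free_oracle_equivalence(self):
        """Gauss-Newton reaches the same objective value as a derivative-free
        minimizer of the identical function (small random instances)."""
        from scipy.optimize import minimize

        from livestock3d.transforms import PoseIncrement, apply_increment

        import trimesh as tmlib

        mesh = TriMesh(*map(np.array, (lambda s: (s.vertices, s.faces))(
            tmlib.creation.icosphere(subdivisions=3, radius=0.4))))
        q = MeshDistanceQuery(mesh)
        cfg = RegistrationConfig(kr=0.1, kt=0.1, inner_iterations=25,
                                 inner_step_tol=1e-11)
        r = np.random.default_rng(7)
        for trial in range(5):
            pts = mesh.vertices[r.choice(len(mesh.vertices), 200, replace=False)] \
                + r.normal(0, 0.0002, (200, 3))
            T0 = RigidTransform.from_rotation_translation(
                Rotation.from_rotvec(r.uniform(-0.01, 0.01, 3)).as_matrix(),
                r.uniform(-0.01, 0.01, 3),
            )
            gn = align_camera_to_mesh(pts, T0, T0, q, cfg)
            e_gn = _camera_objective(pts, gn, T0, q, cfg)

            def f(x):
                try:
                    T = apply_increment(PoseIncrement.from_array(x), T0)
                    return _camera_objective(pts, T, T0, q, cfg)
                except ValueError:  # outside the small-angle regime
                    return 1e9

            res = minimize(f, np.zeros(6), method="Powell",
                           options={"xtol": 1e-11, "ftol": 1e-13, "maxiter": 30000})
            assert e_gn <= res.fun * (1 + 1e-4) + 1e-15


class TestInterleavedFixedPoint:
    def test_truth_is_a_fixed_point(self):
        """Zero perturbation, zero noise: the interleaved loop leaves the
        poses at truth (sub-mm, hundredth-degree scale)."""
        import warnings

        from livestock3d.evaluate import pose_set_error
        from livestock3d.registration import run_interleaved
        from livestock3d.simulate import (
            SceneConfig, generate_scene, perturb_and_degrade,
        )

        cfg = SceneConfig(n_cameras=6, width=160, height=120, animal_voxel=0.03)
        scene = generate_scene(cfg, seed=21)
        rig = perturb_and_degrade(scene, 0.0, 0.0, 0.0, seed=22,
                                  K=cfg.intrinsics())
        rcfg = RegistrationConfig(
            depth_intermediate=7, depth_final=7, max_iterations=6,
            max_points_per_camera=1200,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_interleaved(rig, rcfg)
        e = pose_set_error(res.poses, [c.T_true for c in rig.cameras],
                           align_gauge=False)
        assert e.mean_translation_mm < 1.0
        assert e.mean_rotation_deg < 0.05


class TestResidualMetrics:
    def test_cloud_on_mesh_zero(self):
        mesh = plane_mesh()
        pts = mesh.vertices[::2]
        rig = make_rig([pts, mesh.vertices[1::2]])
        m = residual_metrics(rig, mesh)
        assert m.point_to_plane_mm == pytest.approx(0.0, abs=1e-9)

    def test_offset_plane_both_metrics_equal_offset(self):
        mesh = plane_mesh()
        d = 0.004
        a = mesh.vertices[::2] + [0, 0, d]
        b = mesh.vertices[1::2] + [0, 0, d]
        rig = make_rig([a, b])
        m = residual_metrics(rig, mesh)
        assert m.point_to_plane_mm == pytest.approx(d * 1000, rel=1e-6)
        assert m.point_to_point_mm >= m.point_to_plane_mm

    def test_jittered_plane_p2plane_below_p2point(self, rng):
        """Point-to-plane is the smaller metric on noisy dense planes."""
        mesh = plane_mesh(half=0.5, step=0.02)
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = mesh.vertices[::2] + r.normal(0, 0.001, (len(mesh.vertices[::2]), 3))
            b = mesh.vertices[1::2] + r.normal(0, 0.001, (len(mesh.vertices[1::2]), 3))
            m = residual_metrics(make_rig([a, b]), mesh)
            wins += m.point_to_plane_mm < m.point_to_point_mm
        assert wins == 20


class TestEvaluateObjective:
    def test_zero_at_perfect_alignment_without_anchorcost(self):
        mesh = plane_mesh()
        a = mesh.vertices[::2]
        b = mesh.vertices[1::2]
        rig = make_rig([a, b])
        cfg = RegistrationConfig(kr=0.0, kt=0.0)
        val = evaluate_objective(rig, cfg=cfg)
        # residuals are point-to-plane to the *other* camera's points: flat
        # plane -> zero
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_saturation_caps_far_points(self):
        a = np.zeros((10, 3))
        b = np.tile([1.0, 0, 0], (10, 1))
        rig = make_rig([a, b])
        cfg = RegistrationConfig(kr=0.0, kt=0.0, overlap_threshold=5.0)
        val = evaluate_objective(rig, cfg=cfg)
        assert val == pytest.approx(20 * 0.14**2)


class TestCemMinimize:
    def test_convex_sanity_12_params(self):
        lo, hi = -np.ones(12) * 0.1, np.ones(12) * 0.1
        best, trace = cem_minimize(
            lambda x: float(np.sum(x**2)), lo, hi,
            population=200, iterations=50, seed=3,
        )
        assert np.sum(best**2) < 1e-3
        assert trace[-1] <= trace[0]

    def test_deterministic_given_seed(self):
        lo, hi = -np.ones(4), np.ones(4)
        f = lambda x: float(np.sum((x - 0.3) ** 2))
        a = cem_minimize(f, lo, hi, population=50, iterations=10, seed=9)
        b = cem_minimize(f, lo, hi, population=50, iterations=10, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError, match="population"):
            cem_minimize(lambda x: 0.0, -np.ones(2), np.ones(2),
                         population=3, iterations=1, seed=0)
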