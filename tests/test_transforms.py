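"""Rigid-transform algebra, the small-angle linearization and the anchor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from livestock3d.transforms import (
    PoseIncrement,
    RegularizerWeights,
    RigidTransform,
    apply_increment,
    extract_increment,
    gamma,
    increment_matrix,
    rigid_from_correspondences,
)

ANGLES = st.floats(-0.03, 0.03)  # combined rotation stays within ~3 degrees
SHIFTS = st.floats(-0.1, 0.1)


def make_pose(rotvec, t):
    return RigidTransform.from_rotation_translation(
        Rotation.from_rotvec(rotvec).as_matrix(), t
    )


class TestRigidTransform:
    def test_rejects_bad_last_row(self):
        m = np.eye(4)
        m[3, 0] = 1e-12
        with pytest.raises(ValueError, match="last row"):
            RigidTransform(m)

    def test_rejects_non_rotation(self):
        m = np.eye(4)
        m[0, 0] = 2.0
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(m)

    def test_inverse_compose_identity(self):
        T = make_pose([0.3, -0.2, 0.5], [1.0, 2.0, -0.5])
        assert (T @ T.inverse()).almost_equal(RigidTransform.identity(), 1e-12)

    def test_apply_matches_matrix_product(self, rng):
        T = make_pose([0.1, 0.2, -0.3], [0.5, 0.0, 1.0])
        p = rng.normal(size=(7, 3))
        hom = np.concatenate([p, np.ones((7, 1))], axis=1)
        expected = (T.matrix @ hom.T).T[:, :3]
        np.testing.assert_allclose(T.apply(p), expected, atol=1e-12)


class TestApplyIncrement:
    def test_zero_increment_is_identity(self):
        T = RigidTransform.identity()
        out = apply_increment(PoseIncrement.zero(), T)
        assert out.almost_equal(T, 1e-12)

    def test_pure_translation(self):
        out = apply_increment(
            PoseIncrement(0, 0, 0, 0.01, 0, 0), RigidTransform.identity()
        )
        np.testing.assert_allclose(out.translation, [0.01, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out.rotation, np.eye(3), atol=1e-12)

    def test_small_rotation_matches_rodrigues(self):
        # oracle: closed-form rotation of 0.02 rad about x
        out = apply_increment(
            PoseIncrement(0.02, 0, 0, 0, 0, 0), RigidTransform.identity()
        )
        exact = Rotation.from_rotvec([0.02, 0, 0]).as_matrix()
        assert np.linalg.norm(out.rotation - exact) < 2e-4

    def test_non_finite_increment_rejected(self):
        with pytest.raises(ValueError):
            PoseIncrement(np.nan, 0, 0, 0, 0, 0)

    def test_linearization_matrix_layout(self):
        m = increment_matrix(PoseIncrement(0.01, 0.02, 0.03, 1, 2, 3))
        # skew pattern: alpha about x, beta about y, gamma about z
        expected = np.array(
            [[1, -0.03, 0.02, 1], [0.03, 1, -0.01, 2],
             [-0.02, 0.01, 1, 3], [0, 0, 0, 1]]
        )
        np.testing.assert_allclose(m, expected)


class TestExtractIncrement:
    def test_identity_gives_zero(self):
        xi = extract_increment(RigidTransform.identity())
        assert np.all(xi.as_array() == 0)

    def test_pure_translation_read_directly(self):
        T = make_pose([0, 0, 0], [0.01, 0.02, 0.02])
        xi = extract_increment(T)
        np.testing.assert_allclose(
            xi.as_array(), [0, 0, 0, 0.01, 0.02, 0.02], atol=1e-15
        )

    def test_small_rotation_recovers_angle(self):
        # oracle: matrix log of an exact 0.01 rad rotation about z
        T = make_pose([0, 0, 0.01], [0, 0, 0])
        xi = extract_increment(T)
        assert abs(xi.gamma - 0.01) < 1e-6
        assert abs(xi.alpha) < 1e-9 and abs(xi.beta) < 1e-9

    def test_large_rotation_rejected(self):
        T = make_pose([0, 0, 0.5], [0, 0, 0])
        with pytest.raises(ValueError, match="linearization"):
            extract_increment(T)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=ANGLES, b=ANGLES, g=ANGLES, x=SHIFTS, y=SHIFTS, z=SHIFTS)
    def test_roundtrip_small_poses(self, a, b, g, x, y, z):
        T = make_pose([a, b, g], [x, y, z])
        back = apply_increment(extract_increment(T), RigidTransform.identity())
        assert np.linalg.norm(back.matrix - T.matrix) < 1e-4


class TestGamma:
    W1 = RegularizerWeights(1.0, 1.0)

    def test_zero_at_anchor(self):
        T = make_pose([0.01, 0, 0.02], [0.3, 0, 0])
        assert gamma(T, T, self.W1) <= 1e-30

    def test_pure_translation_value(self):
        Ti = make_pose([0, 0, 0], [0.01, 0.02, 0.02])
        assert gamma(Ti, RigidTransform.identity(), self.W1) == pytest.approx(9.0e-4)

    def test_small_rotation_value(self):
        # oracle: extract exact params of the closed-form rotation, plug in
        Ti = make_pose([0, 0, 0.01], [0, 0, 0])
        w = RegularizerWeights(2.0, 1.0)
        assert gamma(Ti, RigidTransform.identity(), w) == pytest.approx(
            2.0e-4, abs=1e-8
        )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            RegularizerWeights(-1.0, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=ANGLES, x=SHIFTS, ga=ANGLES, gx=SHIFTS)
    def test_frame_invariance(self, a, x, ga, gx):
        """Gamma depends only on the relative transform, not the world frame."""
        w = RegularizerWeights(3.0, 7.0)
        Ti = make_pose([a, -a, a / 2], [x, 0.0, -x])
        Ti0 = make_pose([a / 3, 0, 0], [0, x / 2, 0])
        G = make_pose([ga, 2 * ga, -ga], [gx, -gx, 2 * gx])
        v1 = gamma(Ti, Ti0, w)
        v2 = gamma(G @ Ti, G @ Ti0, w)
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestLinearizationBound:
    def test_within_three_degrees(self):
        """Exhaustive grid: L(xi) rotation block vs exact rotation, <= 0.01."""
        angles = np.radians(np.linspace(-3, 3, 13))
        worst = 0.0
        for a in angles:
            for b in angles:
                for g in angles:
                    lin = increment_matrix(PoseIncrement(a, b, g, 0, 0, 0))[:3, :3]
                    exact = Rotation.from_rotvec([a, b, g]).as_matrix()
                    worst = max(worst, np.linalg.norm(lin - exact))
        assert worst <= 0.01


class TestKabsch:
    def test_recovers_known_transform(self, rng):
        T = make_pose([0.4, -0.1, 0.7], [0.2, -0.5, 1.0])
        b = rng.normal(size=(6, 3))
        a = T.apply(b)
        est = rigid_from_correspondences(a, b)
        assert np.abs(est.matrix - T.matrix).max() < 1e-9
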