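import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from physikin import skeleton as sk


def fk(model, theta, lengths=None, root=None):
    if lengths is None:
        lengths = model.default_lengths
    return sk.forward_kinematics(model, theta, lengths, root)


class TestStructure:
    def test_counts(self, model):
        assert model.n_joints == 22
        assert model.n_lengths == 12
        assert len(model.jcp_map) == 15

    def test_group_sizes_and_shared_parameters(self, model):
        assert model.group_sizes() == {"base": 3, "leg": 8, "arm": 8,
                                       "trunk": 3}
        from physikin.tuning import PARAM_KEYS, joint_param_map
        pmap = joint_param_map(model)
        # 11 shared factors: 4 leg, 4 arm, 2 base-link (one of which
        # drives the root translation), 1 trunk+clavicles
        assert len(PARAM_KEYS) == 11
        keys = {model.joints[j].tuning_key for j in range(22)}
        assert len([k for k in keys if k.startswith("leg")]) == 4
        assert len([k for k in keys if k.startswith("arm")]) == 4
        # left/right joints share the same parameter
        for left, right in [("hip_l_flex", "hip_r_flex"),
                            ("knee_l", "knee_r"),
                            ("sh_l_abd", "sh_r_abd"),
                            ("elbow_l", "elbow_r")]:
            assert pmap[model.joint_index(left)] == \
                pmap[model.joint_index(right)]

    def test_topological_order(self, model):
        for i, js in enumerate(model.joints):
            assert js.parent < i
        # every frame reachable from the root
        assert model.ancestors[:, 0:3].any(axis=1).all() or \
            (model.ancestors.sum(axis=1) >= 1).all()

    def test_limits_well_formed(self, model):
        lo, hi = model.limits
        assert np.all(lo < hi)
        assert np.all(lo <= 0) and np.all(hi >= 0)  # rest posture feasible

    def test_non_positive_length_rejected(self):
        bad = sk.DEFAULT_ANTHROPOMETRY.copy()
        bad[3] = 0.0
        with pytest.raises(ValueError, match="shank_r"):
            sk.build_default_skeleton(bad)

    def test_uniform_lengths_build(self):
        m = sk.build_default_skeleton(np.full(12, 0.5))
        assert m.n_joints == 22 and len(m.jcp_map) == 15


class TestForwardKinematics:
    def test_reference_posture_standing(self, model):
        """theta = 0 is quiet standing: head up, arms hanging, all
        centers in the frontal plane."""
        p = fk(model, np.zeros(22), root=np.zeros(3))
        assert np.allclose(p[:, 2], 0.0, atol=1e-12)  # frontal plane
        names = sk.JCP_INDEX
        assert p[names["spine_shoulder"], 1] > p[names["spine_base"], 1]
        assert p[names["ankle_r"], 1] < p[names["knee_r"], 1] < \
            p[names["hip_r"], 1]
        assert p[names["wrist_r"], 1] < p[names["shoulder_r"], 1]
        # hip-to-knee distance is exactly the thigh length
        d = np.linalg.norm(p[names["hip_r"]] - p[names["knee_r"]])
        assert d == pytest.approx(model.default_lengths[1], abs=1e-15)

    def test_single_knee_rotation_closed_form(self, model):
        """90 deg knee flexion rotates the shank vector about the knee
        axis; every other center stays put."""
        p0 = fk(model, np.zeros(22))
        theta = np.zeros(22)
        theta[model.joint_index("knee_r")] = np.pi / 2
        p1 = fk(model, theta)
        i_knee, i_ankle = sk.JCP_INDEX["knee_r"], sk.JCP_INDEX["ankle_r"]
        shank = model.default_lengths[3]
        # shank (0,-L,0) rotated +90 deg about +x becomes (0,0,-L)
        expected = p0[i_knee] + np.array([0.0, 0.0, -shank])
        np.testing.assert_allclose(p1[i_ankle], expected, atol=1e-12)
        moved = np.abs(p1 - p0).max(axis=1) > 1e-12
        assert list(np.flatnonzero(moved)) == [i_ankle]

    def test_subtree_independence(self, model, rng):
        """Angles in one limb do not move centers of another branch."""
        lo, hi = model.limits
        base = rng.uniform(lo / 2, hi / 2)
        other = base.copy()
        for name in ["sh_r_abd", "sh_r_flex", "sh_r_rot", "elbow_r"]:
            other[model.joint_index(name)] = rng.uniform(-0.5, 0.5)
        p_base, p_other = fk(model, base), fk(model, other)
        arm_centers = {sk.JCP_INDEX[n] for n in
                       ["shoulder_r", "elbow_r", "wrist_r"]}
        for m in range(15):
            if m not in arm_centers:
                np.testing.assert_allclose(p_base[m], p_other[m],
                                           atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_segment_rigidity_any_posture(self, model, seed):
        rng = np.random.default_rng(seed)
        lo, hi = model.limits
        theta = rng.uniform(lo, hi)
        p = fk(model, theta)
        for name, pairs in sk.SEGMENT_PAIRS.items():
            expected = model.default_lengths[sk.LENGTH_NAMES.index(name)]
            for a, b in pairs:
                d = np.linalg.norm(p[sk.JCP_INDEX[a]] - p[sk.JCP_INDEX[b]])
                assert d == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_inputs(self, model):
        with pytest.raises(ValueError):
            fk(model, np.zeros(22), lengths=np.zeros(12))
        with pytest.raises(ValueError):
            fk(model, np.full(22, np.nan))


class TestJacobian:
    def test_matches_central_differences(self, model, rng):
        lo, hi = model.limits
        eps = 1e-6
        for _ in range(5):
            theta = rng.uniform(lo / 2, hi / 2)
            _, jt, jl = sk.fk_with_jacobian(model, theta,
                                            model.default_lengths)
            for j in rng.choice(22, size=6, replace=False):
                tp, tm = theta.copy(), theta.copy()
                tp[j] += eps
                tm[j] -= eps
                fd = (fk(model, tp) - fk(model, tm)).ravel() / (2 * eps)
                np.testing.assert_allclose(jt[:, j], fd, atol=1e-5)
            for k in rng.choice(12, size=4, replace=False):
                lp = model.default_lengths.copy()
                lm = model.default_lengths.copy()
                lp[k] += eps
                lm[k] -= eps
                fd = (fk(model, theta, lp)
                      - fk(model, theta, lm)).ravel() / (2 * eps)
                np.testing.assert_allclose(jl[:, k], fd, atol=1e-5)

    def test_kinematic_locality_at_zero_pose(self, model):
        """The knee column only moves centers distal to the knee."""
        _, jt, _ = sk.fk_with_jacobian(model, np.zeros(22),
                                       model.default_lengths)
        col = jt[:, model.joint_index("knee_r")].reshape(15, 3)
        distal = {sk.JCP_INDEX["ankle_r"]}
        for m in range(15):
            if m not in distal:
                np.testing.assert_allclose(col[m], 0.0, atol=1e-15)

    def test_thigh_length_column_is_unit_direction(self, model):
        """At the reference posture the knee center moves straight down
        the thigh axis per unit thigh length."""
        _, _, jl = sk.fk_with_jacobian(model, np.zeros(22),
                                       model.default_lengths)
        col = jl[:, sk.LENGTH_NAMES.index("thigh_r")].reshape(15, 3)
        np.testing.assert_allclose(col[sk.JCP_INDEX["knee_r"]],
                                   [0.0, -1.0, 0.0], atol=1e-12)
        assert np.linalg.norm(col[sk.JCP_INDEX["knee_r"]]) == \
            pytest.approx(1.0, abs=1e-12)

    def test_state_jacobian_blocks(self, model):
        h = sk.measurement_jacobian(model, np.zeros(22),
                                    model.default_lengths)
        assert h.shape == (45, sk.N_STATE)
        # velocity and acceleration columns are identically zero
        assert np.all(h[:, sk.S_DTHETA] == 0)
        assert np.all(h[:, sk.S_DDTHETA] == 0)
        np.testing.assert_allclose(
            h[:, sk.S_ROOT], np.tile(np.eye(3), (15, 1)), atol=1e-15)

    def test_directional_derivative_consistency(self, model, rng):
        lo, hi = model.limits
        theta = rng.uniform(lo / 2, hi / 2)
        p0, jt, _ = sk.fk_with_jacobian(model, theta,
                                        model.default_lengths)
        delta = 1e-7 * rng.standard_normal(22)
        p1 = fk(model, theta + delta)
        np.testing.assert_allclose((p1 - p0).ravel(), jt @ delta,
                                   atol=1e-11)


class TestSerialization:
    def test_yaml_roundtrip(self, model, tmp_path, rng):
        path = tmp_path / "skeleton.yaml"
        sk.save_skeleton(model, path)
        loaded = sk.load_skeleton(path)
        lo, hi = model.limits
        theta = rng.uniform(lo / 2, hi / 2)
        np.testing.assert_allclose(
            fk(model, theta), fk(loaded, theta), atol=1e-12)
        lo2, hi2 = loaded.limits
        np.testing.assert_allclose(lo, lo2, atol=1e-12)
        np.testing.assert_allclose(hi, hi2, atol=1e-12)
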