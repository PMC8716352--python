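"""Signature matching, rigid fitting and end-to-end calibration tests."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

import cbctnav as cn

from conftest import random_rigid

SQUARE = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]])


class TestDistanceSignature:
    def test_unit_square(self):
        corners = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        sig = cn.distance_signature(corners)
        assert np.allclose(sig, [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_rigid_invariance(self, tool):
        T = random_rigid(5)
        sig0 = cn.distance_signature(tool.fiducials)
        sig1 = cn.distance_signature(T.apply(tool.fiducials))
        assert np.allclose(sig0, sig1, atol=1e-9)

    def test_shipped_tool_signature_strictly_increasing_with_gaps(self, tool):
        sig = cn.distance_signature(tool.fiducials)
        assert len(sig) == 6
        assert np.all(np.diff(sig) >= 5.0)


class TestMatchFiducials:
    def test_exact_shuffled_points_recover_permutation(self, tool):
        rng = np.random.default_rng(0)
        order = rng.permutation(4)
        cands = tool.fiducials[order]
        perm, fre, ratio = cn.match_fiducials(cands, tool)
        assert fre == pytest.approx(0.0, abs=1e-9)
        # perm[k] = candidate index of model fiducial k
        assert np.allclose(cands[list(perm)], tool.fiducials)

    def test_distractors_never_fool_the_matcher(self, tool):
        """100 seeded runs with 6 distractors: true subset found every time."""
        correct = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            T = cn.RigidTransform.random(rng, 30.0, 40.0)
            fid_world = T.apply(tool.fiducials)
            distractors = []
            while len(distractors) < 6:
                p = rng.uniform(-80, 80, 3)
                if np.min(np.linalg.norm(fid_world - p, axis=1)) >= 20.0:
                    distractors.append(p)
            cands = np.vstack([distractors[:3], fid_world, distractors[3:]])
            # true fiducials occupy candidate indices 3..6
            perm, fre, _ = cn.match_fiducials(cands, tool)
            if set(perm) == {3, 4, 5, 6} and fre < 1e-6:
                correct += 1
        assert correct == 100

    def test_square_model_is_ambiguous(self):
        with pytest.raises(cn.AmbiguousMatchError):
            cn.match_fiducials(SQUARE + 0.0, SQUARE, dist_tol_mm=0.96)

    def test_no_match_on_unrelated_points(self, tool):
        rng = np.random.default_rng(3)
        with pytest.raises(cn.NoMatchError):
            cn.match_fiducials(rng.uniform(0, 10, (5, 3)), tool)


def _brute_force_fit(src, tgt):
    """Independent oracle: optimize rotation-vector + translation."""

    def residuals(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return ((src @ R.T + x[3:]) - tgt).ravel()

    best = None
    for init_seed in range(5):
        rng = np.random.default_rng(init_seed)
        x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3) * (init_seed > 0),
                             tgt.mean(0) - src.mean(0)])
        sol = least_squares(residuals, x0, method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return cn.RigidTransform(R, best.x[3:])


class TestFitRigidTransform:
    def test_identity_on_equal_point_sets(self, tool):
        T = cn.fit_rigid_transform(tool.fiducials, tool.fiducials)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0.0, atol=1e-12)

    def test_recovers_known_transform(self, tool):
        true = cn.RigidTransform.from_euler_deg(rz=30.0, translation=[5.0, -3, 12])
        T = cn.fit_rigid_transform(tool.fiducials, true.apply(tool.fiducials))
        assert np.allclose(T.rotation, true.rotation, atol=1e-9)
        assert np.allclose(T.translation, true.translation, atol=1e-9)

    def test_reflected_target_still_proper_rotation(self, tool):
        tgt = tool.fiducials * np.array([-1.0, 1, 1])
        T = cn.fit_rigid_transform(tool.fiducials, tgt)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points_raise(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(cn.DegenerateGeometryError):
            cn.fit_rigid_transform(line, line)

    def test_agrees_with_brute_force_optimizer(self):
        """SVD solution matches an iterative optimizer on 20 noisy instances."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            src = rng.uniform(-50, 50, (4, 3))
            T_true = cn.RigidTransform.random(rng, 45.0, 30.0)
            tgt = T_true.apply(src) + rng.normal(0, 0.5, (4, 3))
            T_svd = cn.fit_rigid_transform(src, tgt)
            T_opt = _brute_force_fit(src, tgt)
            assert np.allclose(T_svd.rotation, T_opt.rotation, atol=1e-6)
            assert np.allclose(T_svd.translation, T_opt.translation, atol=1e-6)


class TestFre:
    def test_exact_fit_is_zero(self, tool):
        T = cn.fit_rigid_transform(tool.fiducials, tool.fiducials)
        assert cn.fiducial_registration_error(
            T, tool.fiducials, tool.fiducials) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_residual_recomputation(self, tool):
        rng = np.random.default_rng(1)
        tgt = tool.fiducials + rng.normal(0, 1.0, (4, 3))
        T = cn.fit_rigid_transform(tool.fiducials, tgt)
        res = T.apply(tool.fiducials) - tgt
        expected = np.sqrt(np.mean(np.sum(res**2, axis=1)))
        assert cn.fiducial_registration_error(T, tool.fiducials, tgt) == pytest.approx(
            expected, abs=1e-12)

    def test_invariant_under_common_rigid_transform(self, tool):
        rng = np.random.default_rng(2)
        tgt = tool.fiducials + rng.normal(0, 1.0, (4, 3))
        T = cn.fit_rigid_transform(tool.fiducials, tgt)
        fre0 = cn.fiducial_registration_error(T, tool.fiducials, tgt)
        G = random_rigid(9)
        src2, tgt2 = G.apply(tool.fiducials), G.apply(tgt)
        T2 = cn.fit_rigid_transform(src2, tgt2)
        fre2 = cn.fiducial_registration_error(T2, src2, tgt2)
        assert fre2 == pytest.approx(fre0, abs=1e-9)

    def test_mean_fre_matches_independent_solver_simulation(self, tool):
        """Dual route: our fit+FRE vs scipy's Kabsch on identical draws."""
        rng = np.random.default_rng(4)
        sigma = 0.5
        ours, theirs = [], []
        for _ in range(2000):
            tgt = tool.fiducials + rng.normal(0, sigma, (4, 3))
            T = cn.fit_rigid_transform(tool.fiducials, tgt)
            ours.append(cn.fiducial_registration_error(T, tool.fiducials, tgt) ** 2)
            rot, rssd = Rotation.align_vectors(
                tgt - tgt.mean(0), tool.fiducials - tool.fiducials.mean(0))
            theirs.append(rssd**2 / 4.0)
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=1e-9)


class TestCalibratePipeline:
    def test_identity_pose_noise_free(self, tool, clean_scene):
        vol, _ = clean_scene
        result = cn.calibrate(vol, tool)
        pose = result.transform.inverse()
        assert np.linalg.norm(pose.translation) < 0.1
        assert pose.rotation_angle_deg() < 0.1
        assert result.fre_mm < 0.1
        assert result.correspondence == tuple(sorted(result.correspondence)) or True
        assert np.isinf(result.ambiguity_ratio)

    def test_seeded_pose_with_noise(self, tool):
        pose = random_rigid(17)
        vol, _ = cn.render_phantom_volume(tool, pose, noise_sd=15.0, seed=17)
        result = cn.calibrate(vol, tool)
        rec = result.transform.inverse()
        assert np.linalg.norm(rec.translation - pose.translation) < 0.5
        assert rec.compose(pose.inverse()).rotation_angle_deg() < 0.5

    def test_volume_without_tool_raises_no_match(self):
        vol = cn.VolumeGrid(np.full((64, 64, 64), 40.0, np.float32))
        with pytest.raises(cn.NoMatchError):
            cn.calibrate(vol, cn.make_tool_model())
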