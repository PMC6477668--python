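import numpy as np
import pytest

from momentarms import (GaitTrajectory, PerturbationSpec, isolated_joint_profile,
                        moment_arm_vs_length, normalize_profile,
                        reachable_surface, sensitivity_analysis,
                        stepping_profile)

from conftest import make_muscle

TWO_PI = 2 * np.pi


def flat_trajectories(chain, **offsets):
    return {name: GaitTrajectory(name, offset=offsets.get(name, 0.0),
                                 terms=[(0.0, TWO_PI, 0.0)])
            for name in chain.joint_names()}


class TestIsolatedProfile:
    def test_sample_count(self, three_joint_chain, hip_muscle):
        prof = isolated_joint_profile(three_joint_chain, hip_muscle, "hip",
                                      (-30.0, 30.0, 1.0))
        assert len(prof.samples) == 61
        np.testing.assert_allclose(prof.abscissa[:3], [-30, -29, -28])

    def test_pulley_constant_by_construction(self, pulley_fixture):
        """Sweeping the proximal joint rigidly co-rotates the spanned
        assembly, so the arm about the distal joint is constant at +d."""
        fix = pulley_fixture
        prof = isolated_joint_profile(fix.chain, fix.muscle("belt"), "pulley",
                                      (-30.0, 30.0, 1.0), sweep_joint="drive")
        assert prof.r.max() - prof.r.min() < 1e-6
        np.testing.assert_allclose(prof.r, 2.0, atol=1e-9)

    def test_biarticular_depends_on_adjacent_joint(self, rat_fixture):
        fix = rat_fixture
        ham = fix.muscle("hamstring")
        kwargs = dict(sweep=(-30.0, 20.0, 2.0))
        p0 = isolated_joint_profile(fix.chain, ham, "knee",
                                    fixed_angles={"hip": 0.0}, **kwargs)
        p1 = isolated_joint_profile(fix.chain, ham, "knee",
                                    fixed_angles={"hip": 30.0}, **kwargs)
        assert np.max(np.abs(p1.r - p0.r)) > 0.1

    def test_monoarticular_invariant_to_other_joints(self, rat_fixture):
        fix = rat_fixture
        mono = fix.muscle("knee_extensor")
        kwargs = dict(sweep=(-40.0, 20.0, 5.0))
        p0 = isolated_joint_profile(fix.chain, mono, "knee",
                                    fixed_angles={"hip": -20.0, "ankle": 0.0},
                                    **kwargs)
        p1 = isolated_joint_profile(fix.chain, mono, "knee",
                                    fixed_angles={"hip": 30.0, "ankle": -30.0},
                                    **kwargs)
        np.testing.assert_allclose(p0.r, p1.r, atol=1e-9)

    def test_sweep_outside_limits_rejected(self, three_joint_chain, hip_muscle):
        with pytest.raises(ValueError, match="limits"):
            isolated_joint_profile(three_joint_chain, hip_muscle, "hip",
                                   (-90.0, 90.0, 1.0))

    def test_non_spanning_muscle_rejected(self, three_joint_chain, hip_muscle):
        with pytest.raises(ValueError, match="does not cross"):
            isolated_joint_profile(three_joint_chain, hip_muscle, "ankle",
                                   (-10.0, 10.0, 1.0))


class TestSteppingProfile:
    def test_loop_closure(self, rat_fixture):
        """Periodic gait: the arm returns to its t=0 value as t -> 1."""
        from momentarms import moment_arm, pose_at

        fix = rat_fixture
        ham = fix.muscle("hamstring")
        prof = stepping_profile(fix.chain, ham, "knee", fix.trajectories, 100)
        r_start = prof.samples[0].r
        pose_end = pose_at(fix.chain, fix.trajectories, 1.0)
        r_end = moment_arm(ham, pose_end, fix.chain, "knee")
        assert abs(r_end - r_start) < 1e-6

    def test_constant_trajectories_give_constant_profile(self, three_joint_chain,
                                                         hip_muscle):
        trajs = flat_trajectories(three_joint_chain, hip=15.0)
        prof = stepping_profile(three_joint_chain, hip_muscle, "hip", trajs, 20)
        assert prof.r.max() - prof.r.min() < 1e-12

    def test_same_angle_two_moment_arms(self, rat_fixture):
        """A biarticular arm at a repeated spanned-joint angle differs when
        the adjacent joint sits at a different angle — the reason a simple
        angle-indexed lookup table is ambiguous for biarticular muscles."""
        from scipy.optimize import brentq

        from momentarms import moment_arm, pose_at

        fix = rat_fixture
        ham = fix.muscle("hamstring")
        knee = fix.trajectories["knee"]
        t1 = 0.1
        target = knee(t1)
        # find a second stride time with the identical knee angle
        t2 = brentq(lambda t: knee(t) - target, 0.45, 0.95, xtol=1e-12)
        hip = fix.trajectories["hip"]
        assert abs(hip(t1) - hip(t2)) > 5.0
        r1 = moment_arm(ham, pose_at(fix.chain, fix.trajectories, t1),
                        fix.chain, "knee")
        r2 = moment_arm(ham, pose_at(fix.chain, fix.trajectories, t2),
                        fix.chain, "knee")
        assert abs(r1 - r2) > 0.05

    def test_n_samples_validation(self, rat_fixture):
        fix = rat_fixture
        with pytest.raises(ValueError, match="n_samples"):
            stepping_profile(fix.chain, fix.muscle("hamstring"), "knee",
                             fix.trajectories, 1)


class TestMomentArmVsLength:
    def test_output_shape_and_closure(self, rat_fixture):
        fix = rat_fixture
        loop = moment_arm_vs_length(fix.chain, fix.muscle("gastrocnemius"),
                                    "ankle", fix.trajectories, n_samples=80)
        assert len(loop.t) == 80
        assert loop.normalized and not loop.constant_length
        assert loop.length.min() == pytest.approx(0.0)
        assert loop.length.max() == pytest.approx(1.0)
        assert loop.r.min() == pytest.approx(0.0)
        assert loop.r.max() == pytest.approx(1.0)

    def test_constant_length_muscle_flagged(self, two_body_chain):
        """A muscle inserting on the rotation axis keeps constant length; its
        raw length is emitted instead of dividing by a zero range."""
        m = make_muscle("const", ("base", (-10.0, 5.0, 0.0)),
                        ("link", (0.0, 0.0, 2.0)))
        trajs = {"hinge": GaitTrajectory("hinge", offset=0.0,
                                         terms=[(30.0, TWO_PI, 0.0)])}
        loop = moment_arm_vs_length(two_body_chain, m, "hinge", trajs, 24)
        assert loop.constant_length
        assert loop.length.max() - loop.length.min() < 1e-9
        assert loop.length[0] > 1.0  # raw mm, not normalised


class TestSensitivity:
    def test_zero_magnitude_reproduces_baseline_exactly(self, planar_fixture):
        fix = planar_fixture
        spec = PerturbationSpec("cord", 0, (0.0, 1.0, 0.0), magnitude=0.0)
        res = sensitivity_analysis(fix.chain, fix.muscle("cord"), "hinge",
                                   spec, (-30.0, 30.0, 2.0))
        assert res.max_abs_deviation == 0.0
        assert np.array_equal(res.baseline.r, res.perturbed_plus.r)
        assert np.array_equal(res.baseline.r, res.perturbed_minus.r)

    def test_tiny_perturbation_continuity(self, planar_fixture):
        fix = planar_fixture
        spec = PerturbationSpec("cord", 0, (0.0, 1.0, 0.0), magnitude=1e-9)
        res = sensitivity_analysis(fix.chain, fix.muscle("cord"), "hinge",
                                   spec, (-30.0, 30.0, 2.0))
        assert res.max_abs_deviation < 1e-6

    def test_pulley_shift_along_moment_arm_direction(self, pulley_fixture):
        """Moving an attachment 1 mm directly away from the joint along the
        moment-arm direction shifts r by ~ +1 mm at every sweep angle."""
        fix = pulley_fixture
        spec = PerturbationSpec("belt", 0, (0.0, -1.0, 0.0), magnitude=1.0)
        res = sensitivity_analysis(fix.chain, fix.muscle("belt"), "pulley",
                                   spec, (-30.0, 30.0, 2.0), sweep_joint="drive")
        shift = res.perturbed_plus.r - res.baseline.r
        np.testing.assert_allclose(shift, 1.0, atol=0.01)

    def test_perturbation_parallel_to_segment_is_null(self, pulley_fixture):
        fix = pulley_fixture
        spec = PerturbationSpec("belt", 0, (1.0, 0.0, 0.0), magnitude=1.0)
        res = sensitivity_analysis(fix.chain, fix.muscle("belt"), "pulley",
                                   spec, (-30.0, 30.0, 2.0), sweep_joint="drive")
        assert res.max_abs_deviation < 0.01

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            PerturbationSpec("m", 0, (0.0, 2.0, 0.0))

    def test_attachment_off_free_segment_rejected(self, rat_fixture):
        fix = rat_fixture
        tib = fix.muscle("ankle_dorsiflexor")  # attachments 0,1 on tibia, 2 on foot
        spec = PerturbationSpec("ankle_dorsiflexor", 0, (0.0, 1.0, 0.0))
        with pytest.raises(ValueError, match="free segment"):
            sensitivity_analysis(fix.chain, tib, "ankle", spec, (-20.0, 20.0, 5.0))


class TestNormalizeProfile:
    def test_femur_scaling(self, three_joint_chain):
        m = make_muscle("m", ("pelvis", (-10.0, 3.575, 0.0)),
                        ("femur", (10.0, 3.575, 0.0)))
        prof = isolated_joint_profile(three_joint_chain, m, "hip", (0.0, 0.0, 1.0))
        assert abs(prof.samples[0].r) == pytest.approx(3.575, abs=1e-9)
        norm = normalize_profile(prof, 35.75)
        assert abs(norm.samples[0].r) == pytest.approx(0.1, abs=1e-9)
        assert norm.normalization == "femur_length"
        assert norm.reference_length == 35.75

    def test_unit_length_identity(self, three_joint_chain, hip_muscle):
        prof = isolated_joint_profile(three_joint_chain, hip_muscle, "hip",
                                      (-10.0, 10.0, 5.0))
        norm = normalize_profile(prof, 1.0)
        np.testing.assert_array_equal(norm.r, prof.r)

    def test_double_normalization_rejected(self, three_joint_chain, hip_muscle):
        prof = isolated_joint_profile(three_joint_chain, hip_muscle, "hip",
                                      (-10.0, 10.0, 5.0))
        norm = normalize_profile(prof, 35.75)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_profile(norm, 35.75)

    def test_nonpositive_length_rejected(self, three_joint_chain, hip_muscle):
        prof = isolated_joint_profile(three_joint_chain, hip_muscle, "hip",
                                      (-10.0, 10.0, 5.0))
        with pytest.raises(ValueError, match="> 0"):
            normalize_profile(prof, 0.0)

    def test_linearity(self, three_joint_chain, hip_muscle):
        prof = isolated_joint_profile(three_joint_chain, hip_muscle, "hip",
                                      (-10.0, 10.0, 5.0))
        np.testing.assert_allclose(normalize_profile(prof, 20.0).r,
                                   0.5 * normalize_profile(prof, 10.0).r,
                                   atol=1e-12)


class TestReachableSurface:
    def test_monoarticular_rejected(self, rat_fixture):
        fix = rat_fixture
        mono = fix.muscle("knee_extensor")
        prof = stepping_profile(fix.chain, mono, "knee", fix.trajectories, 10)
        with pytest.raises(ValueError, match="biarticular"):
            reachable_surface(fix.chain, mono, prof)

    def test_degenerate_trajectory_single_cell(self, rat_fixture):
        fix = rat_fixture
        ham = fix.muscle("hamstring")
        trajs = flat_trajectories(fix.chain, hip=10.0, knee=-15.0)
        prof = stepping_profile(fix.chain, ham, "knee", trajs, 8)
        surf = reachable_surface(fix.chain, ham, prof)
        assert surf.r.shape == (1, 1)
        assert surf.mask.all()
        # single grid cell reproduces the stepping sample exactly
        assert surf.r[0, 0] == pytest.approx(prof.samples[0].r, abs=1e-9)

    def test_adjacent_joint_gradient_nonzero(self, rat_fixture):
        """Somewhere on the grid the arm varies along the adjacent-joint axis."""
        fix = rat_fixture
        ham = fix.muscle("hamstring")
        prof = stepping_profile(fix.chain, ham, "knee", fix.trajectories, 60)
        surf = reachable_surface(fix.chain, ham, prof, resolution=2.0,
                                 mask_distance_cells=2.0)
        assert surf.joint_pair == ("hip", "knee")
        grad = np.abs(np.diff(surf.r, axis=0))  # along hip (adjacent) axis
        assert np.nanmax(grad) > 0.0

    def test_grid_matches_engine_on_mask(self, rat_fixture):
        from momentarms import forward_kinematics, moment_arm

        fix = rat_fixture
        ham = fix.muscle("hamstring")
        prof = stepping_profile(fix.chain, ham, "knee", fix.trajectories, 30)
        surf = reachable_surface(fix.chain, ham, prof, resolution=5.0)
        i, k = np.argwhere(surf.mask)[0]
        angles = {"hip": float(surf.theta1[i]), "knee": float(surf.theta2[k]),
                  "ankle": 0.0}
        pose = forward_kinematics(fix.chain, angles, ignore_limits=True)
        assert surf.r[i, k] == pytest.approx(
            moment_arm(ham, pose, fix.chain, "knee"), abs=1e-12)
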