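"""Generator properties: scripted sessions, trial scripts and IMU/force rendering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from reachkin.core_io import TrialCondition
from reachkin.orientation import FusionParams, estimate_orientation
from reachkin.core_io import resample_stream
from reachkin.synthetic import (
    ChainModel,
    GroundTruth,
    JointTrajectory,
    NoiseConfig,
    body_rates,
    condition_metric_means,
    minimum_jerk_series,
    render_forces,
    render_imu,
    script_calibration_session,
    script_reach_trial,
    segment_orientations,
)
from reachkin.segmentation import PhaseEvents

ZERO = NoiseConfig.zero(seed=5)


class TestMinimumJerk:
    def test_passes_through_knots_and_holds_ends(self):
        t = np.linspace(-1, 6, 701)
        y = minimum_jerk_series(t, [(0.0, 1.0), (2.0, 5.0), (4.0, -1.0)])
        assert np.allclose(y[t <= 0.0], 1.0)
        assert np.allclose(y[t >= 4.0], -1.0)
        assert abs(y[np.argmin(np.abs(t - 2.0))] - 5.0) < 1e-9

    def test_monotone_between_knots(self):
        t = np.linspace(0, 2, 401)
        y = minimum_jerk_series(t, [(0.0, 0.0), (2.0, 10.0)])
        assert np.all(np.diff(y) >= -1e-12)


@pytest.fixture(scope="module")
def poses():
    return script_calibration_session("left")


class TestCalibrationScripts:
    def test_standing_pose_is_constant(self, poses):
        for arr in poses[9].angles.values():
            assert np.ptp(arr) == 0.0

    def test_hip_flexion_ramps_to_sixty(self, poses):
        tf = poses[10].angles["trunk_flexion"]
        assert tf[0] == 0.0
        assert abs(tf[-1] - 60.0) < 1e-9

    def test_pronation_sweep_isolated_and_wide(self, poses):
        traj = poses[6]
        assert np.ptp(traj.angles["forearm_prosup"]) >= 120.0
        assert np.allclose(traj.angles["elbow_flexext"], 90.0)
        for name, arr in traj.angles.items():
            if name not in ("forearm_prosup", "elbow_flexext"):
                assert np.ptp(arr) == 0.0


class TestReachScripts:
    def test_events_ordered_for_every_condition(self):
        for arm in ("AF", "NAF"):
            for block in ("BL", "BW", "BH"):
                for target in ("Tab1", "Tab2", "Top3", "Top4"):
                    truth = script_reach_trial(TrialCondition(arm, block, target), seed=3)
                    ev = truth.events
                    assert ev.t_start < ev.t_grasp < ev.t_release < ev.t_end

    def test_top_target_has_larger_elbow_excursion(self):
        top = script_reach_trial(TrialCondition("AF", "BH", "Top3"))
        tab = script_reach_trial(TrialCondition("AF", "BH", "Tab1"))

        def disp_rom(tr):
            m = (tr.trajectory.t >= tr.events.t_grasp) & (tr.trajectory.t < tr.events.t_release)
            e = tr.trajectory.angles["elbow_flexext"][m]
            return np.ptp(e)

        assert disp_rom(top) > disp_rom(tab) + 10.0

    def test_seeded_variation_and_determinism(self):
        cond = TrialCondition("NAF", "BW", "Tab2")
        a = script_reach_trial(cond, seed=1)
        b = script_reach_trial(cond, seed=2)
        c = script_reach_trial(cond, seed=1)
        assert not np.array_equal(a.trajectory.angles["elbow_flexext"],
                                  b.trajectory.angles["elbow_flexext"])
        np.testing.assert_array_equal(a.trajectory.angles["elbow_flexext"],
                                      c.trajectory.angles["elbow_flexext"])
        # events stay within the scripted jitter of the nominal timing
        assert abs(a.events.t_grasp - b.events.t_grasp) < 0.5

    def test_movement_time_defaults(self):
        af = script_reach_trial(TrialCondition("AF", "BW", "Tab1"))
        naf = script_reach_trial(TrialCondition("NAF", "BW", "Tab1"))
        assert abs((af.events.t_end - af.events.t_start) - 4.9) < 1e-9
        assert abs((naf.events.t_end - naf.events.t_start) - 2.8) < 1e-9

    def test_condition_means_reproduce_group_values(self):
        af = [condition_metric_means(TrialCondition("AF", b, t))
              for b in ("BL", "BW", "BH") for t in ("Tab1", "Tab2", "Top3", "Top4")]
        naf = [condition_metric_means(TrialCondition("NAF", b, t))
               for b in ("BL", "BW", "BH") for t in ("Tab1", "Tab2", "Top3", "Top4")]
        assert abs(np.mean([m["elbow_rom"] for m in af]) - 44.3) < 0.05
        assert abs(np.mean([m["elbow_rom"] for m in naf]) - 54.2) < 0.05
        assert abs(np.mean([m["trunk_comp"] for m in af]) - 9.4) < 0.05
        top = [m["elbow_rom"] for m in af + naf if False] or [
            condition_metric_means(TrialCondition(a, b, t))["elbow_rom"]
            for a in ("AF", "NAF") for b in ("BL", "BW", "BH") for t in ("Top3", "Top4")
        ]
        assert abs(np.mean(top) - 61.3) < 0.05


def _static_truth(dur=3.0, rate=200.0, **dofs):
    t = np.arange(int(dur * rate) + 1) / rate
    traj = JointTrajectory(t=t, angles={k: np.full_like(t, v) for k, v in dofs.items()})
    ev = PhaseEvents(0.5, 1.0, 1.5, 2.0, method="manual")
    return GroundTruth(trajectory=traj, events=ev, condition=TrialCondition("AF", "BW", "Tab1"))


class TestRenderImu:
    def test_static_pose_reads_bias_and_gravity(self):
        noise = NoiseConfig(0.0, 0.0, 0.01, 0.0, 0.0, seed=9)
        chain = ChainModel()
        sset = render_imu(chain, _static_truth(elbow_flexext=90.0), noise)
        for site, st in sset.streams.items():
            np.testing.assert_allclose(st.gyro, np.tile(noise.gyro_bias(site), (len(st.gyro), 1)),
                                       atol=1e-9)
            np.testing.assert_allclose(np.linalg.norm(st.accel, axis=1), 9.81, atol=1e-9)

    def test_constant_rate_about_sensor_axis(self):
        # trunk torsion at 1 rad/s: the sternum gyro z-axis reads 1.0
        rate = 200.0
        t = np.arange(int(2.0 * rate) + 1) / rate
        traj = JointTrajectory(t=t, angles={"trunk_torsion": np.degrees(1.0) * t})
        truth = GroundTruth(trajectory=traj, events=PhaseEvents(0.2, 0.5, 1.0, 1.5),
                            condition=TrialCondition("AF", "BW", "Tab1"), side="left")
        sset = render_imu(ChainModel(), truth, ZERO)
        gz = sset.streams["sternum"].gyro[5:-5, 2]
        np.testing.assert_allclose(np.abs(gz), 1.0, atol=1e-6)

    def test_gyro_integrates_back_to_orientation(self, clean_subject, clean_trial):
        # strapdown of the rendered noise-free gyro reproduces the rendered
        # orientation trajectory within half a degree
        from reachkin.conventions import SITE_SEGMENT
        from reachkin.orientation import rotation_to_quat

        truth, sset = clean_trial
        site = "lower_arm"
        st = resample_stream(sset.streams[site], 100.0)
        seg = segment_orientations(truth.trajectory, truth.side)
        r_true = seg[SITE_SEGMENT[site]] * clean_subject.chain.mountings[site]
        idx0 = int(round((st.t[0] - truth.trajectory.t[0]) * truth.trajectory.rate))
        out = estimate_orientation(
            st, FusionParams(beta=0.0, use_zupt=False, q0=rotation_to_quat(r_true[idx0]))
        )
        idx = np.clip(
            np.round((out.t - truth.trajectory.t[0]) * truth.trajectory.rate).astype(int),
            0,
            len(truth.trajectory.t) - 1,
        )
        err = np.degrees((out.as_rotation().inv() * r_true[idx]).magnitude())
        assert np.sqrt(np.mean(err**2)) < 0.5

    def test_rendered_rates_match_scripted_joint_velocity(self):
        # pose 6: forearm gyro about x equals the scripted pronosupination rate
        poses = script_calibration_session("left")
        traj = poses[6]
        seg = segment_orientations(traj, "left")
        w = body_rates(seg["lower_arm"], 1.0 / traj.rate)
        scripted = -np.gradient(np.deg2rad(traj.angles["forearm_prosup"]), traj.t)
        rms_ref = np.sqrt(np.mean(scripted**2))
        err = np.sqrt(np.mean((w[:, 0] - scripted) ** 2))
        assert err < 0.02 * rms_ref + 1e-6

    def test_bit_identical_under_same_seed(self):
        truth = script_reach_trial(TrialCondition("AF", "BL", "Top4"), seed=8)
        noise = NoiseConfig(seed=21)
        a = render_imu(ChainModel(), truth, noise, stream_key=3)
        b = render_imu(ChainModel(), truth, noise, stream_key=3)
        for site in a.streams:
            np.testing.assert_array_equal(a.streams[site].gyro, b.streams[site].gyro)
            np.testing.assert_array_equal(a.streams[site].accel, b.streams[site].accel)


class TestRenderForces:
    def test_quiet_before_grasp(self):
        truth = script_reach_trial(TrialCondition("AF", "BW", "Tab1"))
        forces = render_forces(truth, NoiseConfig(seed=2))
        sd = 0.02
        for fc in forces.values():
            pre = fc.force[fc.t < truth.events.t_grasp - 0.2]
            assert np.abs(pre).max() < 3 * sd + 1e-9 or np.percentile(np.abs(pre), 99) < 3 * sd

    def test_plateau_scales_with_block_mass(self):
        heights = {}
        for block in ("BL", "BW", "BH"):
            truth = script_reach_trial(TrialCondition("AF", block, "Tab1"))
            f = render_forces(truth, ZERO)["index"]
            heights[block] = f.force.max()
        assert heights["BH"] > heights["BW"] > heights["BL"]

    def test_zero_noise_minimum_exactly_at_release(self):
        truth = script_reach_trial(TrialCondition("AF", "BH", "Top3"))
        f = render_forces(truth, ZERO)["middle"]
        after_plateau = f.t > truth.events.t_grasp + 0.5
        tmin = f.t[after_plateau][np.argmin(f.force[after_plateau])]
        assert abs(tmin - truth.events.t_release) <= 0.01 + 1e-9
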