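"""Synthetic ground truth: scripted calibration sessions and reach-to-grasp
trials rendered into noisy IMU and fingertip-force signals.

The generator is the forward model of the pipeline's inverse problem.  A
trunk-to-fingertip chain executes minimum-jerk joint trajectories; each
segment's orientation follows from the joint angles, each sensor's from its
mounting rotation; body-frame angular rates and gravity-inclusive specific
forces are then sampled at the hardware rates (gyro 200 Hz, accel 100 Hz)
with white noise and a per-sensor constant gyro bias.

The default trial scripts ARE the study conditions: per-condition
displacement-phase range-of-motion targets equal the reported group means for
the affected/non-affected arm, table/top target heights and the three block
weights, and movement time is 4.9 s (affected) / 2.8 s (non-affected).
Repetition-to-repetition and subject-to-subject variation enter as seeded
Gaussian jitter on the targets and phase durations.

All randomness flows through :class:`NoiseConfig` seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .conventions import (
    DOF_NAMES,
    FINGERS,
    SENSOR_SITES,
    SITE_SEGMENT,
    side_factor,
)
from .core_io import ForceChannel, ImuStream, SensorSet, TrialCondition
from .segmentation import PhaseEvents

GRAVITY_UP = np.array([0.0, 0.0, 9.81])

# neutral orientation of arm/hand/finger anatomical frames: x distal (down),
# y mediolateral, z completing the right-handed triad
_R0 = Rotation.from_matrix(np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]]))

_ARM_SEGMENTS = ("upper_arm", "lower_arm", "hand", "thumb", "index", "middle")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ChainModel:
    """Trunk-to-fingertip kinematic chain with sensor mountings.

    lengths are in meters (conventional adult means); `mountings` maps sensor
    site -> fixed rotation of the sensor frame relative to its segment's
    anatomical frame (v_segment = R_mount @ v_sensor); `positions` maps site
    -> fraction of the segment length at which the sensor sits.
    """

    lengths: dict[str, float] = field(
        default_factory=lambda: {
            "trunk": 0.45,
            "upper_arm": 0.30,
            "lower_arm": 0.26,
            "hand": 0.08,
            "thumb": 0.03,
            "index": 0.04,
            "middle": 0.04,
        }
    )
    shoulder_offset_y: float = 0.18  # lateral hip-to-shoulder offset, m
    mountings: dict[str, Rotation] = field(
        default_factory=lambda: {s: Rotation.identity() for s in SENSOR_SITES}
    )
    positions: dict[str, float] = field(
        default_factory=lambda: {
            "sternum": 0.75,
            "shoulder": 0.98,
            "upper_arm": 0.7,
            "lower_arm": 0.75,
            "hand": 0.5,
            "thumb": 1.0,
            "index": 1.0,
            "middle": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths.values()):
            raise ValueError("segment lengths must be positive")
        for site, m in self.mountings.items():
            M = m.as_matrix()
            if np.max(np.abs(M @ M.T - np.eye(3))) > 1e-9 or np.linalg.det(M) < 0:
                raise ValueError(f"{site}: mounting is not a proper rotation")

    def with_random_mountings(self, rng: np.random.Generator) -> "ChainModel":
        return dataclasses.replace(
            self, mountings={s: Rotation.random(random_state=rng) for s in SENSOR_SITES}
        )


@dataclass
class JointTrajectory:
    """Scripted joint-angle time series, degrees, on a uniform grid."""

    t: np.ndarray
    angles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in DOF_NAMES:
            if name not in self.angles:
                self.angles[name] = np.zeros_like(self.t)
        for name, arr in self.angles.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name}: length mismatch")
            self.angles[name] = arr
        if np.any(self.angles["elbow_flexext"] < -1e-9):
            raise ValueError("generated elbow angle must be non-negative (no hyperextension)")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class GroundTruth:
    trajectory: JointTrajectory
    events: PhaseEvents
    condition: TrialCondition
    side: str = "left"
    analysis_start: float = 0.0
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.trajectory.t
        if not (t[0] <= self.events.t_start and self.events.t_end <= t[-1]):
            raise ValueError("events must lie within the trajectory span")


@dataclass
class NoiseConfig:
    """Sensor-noise model; defaults are consumer-MEMS magnitudes."""

    accel_noise_sd: float = 0.05  # m/s^2
    gyro_noise_sd: float = 0.005  # rad/s
    gyro_bias_sd: float = 0.01  # rad/s, per-sensor constant bias drawn once
    accel_bias_sd: float = 0.0  # m/s^2, per-sensor constant bias
    force_noise_sd: float = 0.02  # unitless FSR noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.accel_noise_sd, self.gyro_noise_sd, self.gyro_bias_sd,
               self.accel_bias_sd, self.force_noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, seed)

    def bias_rng(self, site: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, 101, SENSOR_SITES.index(site)])
        )

    def stream_rng(self, site_or_finger: str, stream_key: int) -> np.random.Generator:
        idx = (SENSOR_SITES + FINGERS).index(site_or_finger)
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, 202, idx, stream_key & 0x7FFFFFFF])
        )

    def gyro_bias(self, site: str) -> np.ndarray:
        return self.bias_rng(site).normal(0.0, self.gyro_bias_sd, 3) if self.gyro_bias_sd else np.zeros(3)

    def accel_bias(self, site: str) -> np.ndarray:
        rng = self.bias_rng(site)
        rng.normal(0.0, 1.0, 3)  # keep draws aligned with gyro_bias
        return rng.normal(0.0, self.accel_bias_sd, 3) if self.accel_bias_sd else np.zeros(3)


# ---------------------------------------------------------------------------
# Minimum-jerk scripting
# ---------------------------------------------------------------------------

def minimum_jerk_series(t: np.ndarray, knots: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise minimum-jerk interpolation through (time, value) knots.

    Between consecutive knots the value follows the quintic
    10 tau^3 - 15 tau^4 + 6 tau^5 blend (zero velocity and acceleration at
    every knot); before the first and after the last knot it holds constant.
    """
    t = np.asarray(t, dtype=float)
    knots = sorted(knots)
    kt = np.array([k[0] for k in knots])
    kv = np.array([k[1] for k in knots])
    if len(kt) > 1 and np.min(np.diff(kt)) <= 0:
        raise ValueError("knot times must be strictly increasing")
    if len(kt) == 1:
        return np.full_like(t, kv[0])
    idx = np.clip(np.searchsorted(kt, t, side="right") - 1, 0, len(kt) - 2)
    t0, t1 = kt[idx], kt[idx + 1]
    tau = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    blend = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    return kv[idx] + (kv[idx + 1] - kv[idx]) * blend


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _shortest_arc(d: np.ndarray) -> Rotation:
    """Minimal rotation taking (0, 0, -1) onto each row of d."""
    e = np.array([0.0, 0.0, -1.0])
    d = np.atleast_2d(d)
    axis = np.cross(np.broadcast_to(e, d.shape), d)
    sin = np.linalg.norm(axis, axis=-1)
    cos = d @ e
    ang = np.arctan2(sin, cos)
    safe = sin > 1e-12
    rv = np.zeros_like(d)
    rv[safe] = axis[safe] / sin[safe, None] * ang[safe, None]
    return Rotation.from_rotvec(rv)


def _upper_arm_direction(flex_deg: np.ndarray, abd_deg: np.ndarray, s: int) -> np.ndarray:
    """Unit direction of the upper-arm x-axis in the trunk frame.

    Built so that the projection-based shoulder-angle definitions recover the
    scripted flexion and abduction exactly (valid for flexion < 90 deg).
    """
    F = np.deg2rad(flex_deg)
    A = np.deg2rad(abd_deg)
    d = np.stack(
        [np.sin(F) * np.cos(A), s * np.cos(F) * np.sin(A), -np.cos(F) * np.cos(A)], axis=-1
    )
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def segment_orientations(traj: JointTrajectory, side: str = "left") -> dict[str, Rotation]:
    """Anatomical-frame orientation of every segment in the global frame."""
    s = side_factor(side)
    a = traj.angles
    trunk = Rotation.from_euler(
        "YXZ",
        np.stack([a["trunk_flexion"], s * a["trunk_lateral"], s * a["trunk_torsion"]], axis=-1),
        degrees=True,
    )
    d = _upper_arm_direction(a["shoulder_flexext"], a["shoulder_abdadd"], s)
    upper = trunk * _shortest_arc(d) * _R0
    # elbow flexion about the mediolateral axis; pronosupination is a twist
    # about the forearm long axis whose physical sense mirrors with the side
    elbow = Rotation.from_euler(
        "YX", np.stack([-a["elbow_flexext"], -s * a["forearm_prosup"]], axis=-1), degrees=True
    )
    lower = upper * elbow
    hand = lower * Rotation.from_euler("y", -a["wrist_flexext"][:, None], degrees=True)
    out = {"trunk": trunk, "upper_arm": upper, "lower_arm": lower, "hand": hand}
    for f in FINGERS:
        out[f] = hand * Rotation.from_euler("y", -a[f"{f}_flexext"][:, None], degrees=True)
    return out


def protocol_frames(seg: dict[str, Rotation], side: str) -> dict[str, Rotation]:
    """Segment frames in the convention the calibration protocol establishes.

    The side-specific axis signs of the ten-pose protocol keep every measured
    frame right-handed on either arm.  For the right arm this yields a trunk
    frame yawed 180 deg about its z-axis (mediolateral axis pointing to the
    subject's right) and an upper-arm frame flipped 180 deg about its x-axis,
    relative to the generator's internal frames; the angle-sign table of the
    kinematics stage is defined against this convention.
    """
    if side_factor(side) == 1:
        return seg
    out = dict(seg)
    out["trunk"] = seg["trunk"] * Rotation.from_euler("z", 180, degrees=True)
    out["upper_arm"] = seg["upper_arm"] * Rotation.from_euler("x", 180, degrees=True)
    return out


def chain_positions(
    chain: ChainModel, seg: dict[str, Rotation], side: str = "left"
) -> dict[str, np.ndarray]:
    """Sensor positions (m, global frame) from forward kinematics."""
    s = side_factor(side)
    ex = np.array([1.0, 0.0, 0.0])
    x = {name: seg[name].apply(ex) for name in _ARM_SEGMENTS}
    L = chain.lengths
    p_shoulder = seg["trunk"].apply(np.array([0.0, s * chain.shoulder_offset_y, L["trunk"]]))
    p_elbow = p_shoulder + L["upper_arm"] * x["upper_arm"]
    p_wrist = p_elbow + L["lower_arm"] * x["lower_arm"]
    p_knuckle = p_wrist + L["hand"] * x["hand"]
    pos = {
        "sternum": seg["trunk"].apply(np.array([0.06, 0.0, chain.positions["sternum"] * L["trunk"]])),
        "shoulder": seg["trunk"].apply(
            np.array([0.0, s * chain.shoulder_offset_y, chain.positions["shoulder"] * L["trunk"]])
        ),
        "upper_arm": p_shoulder + chain.positions["upper_arm"] * L["upper_arm"] * x["upper_arm"],
        "lower_arm": p_elbow + chain.positions["lower_arm"] * L["lower_arm"] * x["lower_arm"],
        "hand": p_wrist + chain.positions["hand"] * L["hand"] * x["hand"],
    }
    for f in FINGERS:
        pos[f] = p_knuckle + chain.positions[f] * L[f] * x[f]
    return pos


def body_rates(rot: Rotation, dt: float) -> np.ndarray:
    """Body-frame angular velocity from an orientation trajectory.

    Central differences of the relative rotation (second-order accurate at
    the sample instants; one-sided at the ends).
    """
    n = len(rot)
    w = np.zeros((n, 3))
    if n < 2:
        return w
    w[1:-1] = (rot[:-2].inv() * rot[2:]).as_rotvec() / (2.0 * dt)
    w[0] = (rot[0].inv() * rot[1]).as_rotvec() / dt
    w[-1] = (rot[-2].inv() * rot[-1]).as_rotvec() / dt
    return w


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_streams(
    chain: ChainModel,
    traj: JointTrajectory,
    side: str,
    noise: NoiseConfig,
    quasi_static: bool,
    stream_key: int,
) -> dict[str, ImuStream]:
    t = traj.t
    if not np.all(np.isfinite(t)) or any(not np.all(np.isfinite(v)) for v in traj.angles.values()):
        raise ValueError("non-finite trajectory")
    dt = 1.0 / traj.rate
    seg = segment_orientations(traj, side)
    accel_world = {}
    if not quasi_static:
        pos = chain_positions(chain, seg, side)
        for site, p in pos.items():
            v = np.gradient(p, dt, axis=0)
            accel_world[site] = np.gradient(v, dt, axis=0)
    streams = {}
    for site in SENSOR_SITES:
        r_sensor = seg[SITE_SEGMENT[site]] * chain.mountings[site]
        omega = body_rates(r_sensor, dt)
        rng = noise.stream_rng(site, stream_key)
        gyro = omega + noise.gyro_bias(site)
        if noise.gyro_noise_sd:
            gyro = gyro + rng.normal(0.0, noise.gyro_noise_sd, gyro.shape)
        a_world = accel_world.get(site, np.zeros(3)) + GRAVITY_UP
        if a_world.ndim == 1:
            a_world = np.tile(a_world, (len(t), 1))
        spec = r_sensor.inv().apply(a_world)
        spec = spec[::2] + noise.accel_bias(site)
        if noise.accel_noise_sd:
            spec = spec + rng.normal(0.0, noise.accel_noise_sd, spec.shape)
        streams[site] = ImuStream(
            site=site,
            t_accel=t[::2],
            accel=spec,
            t_gyro=t,
            gyro=gyro,
            accel_rate=traj.rate / 2.0,
            gyro_rate=traj.rate,
        )
    return streams


def render_imu(
    chain: ChainModel,
    truth: GroundTruth,
    noise: NoiseConfig,
    quasi_static: bool = True,
    stream_key: int = 0,
) -> SensorSet:
    """Render a ground-truth trajectory into an eight-sensor IMU recording.

    Gyro: body-frame angular velocity of each sensor plus its constant bias
    and white noise, at the trajectory rate (200 Hz).  Accel: specific force
    R^T (a - g) at 100 Hz; with `quasi_static` the translational term a is
    zeroed so the accelerometers read pure gravity.
    """
    streams = _render_streams(chain, truth.trajectory, truth.side, noise, quasi_static, stream_key)
    return SensorSet(
        streams=streams,
        forces=render_forces(truth, noise, stream_key=stream_key),
        condition=truth.condition,
        side=truth.side,
        analysis_start=truth.analysis_start,
    )


def render_calibration_session(
    chain: ChainModel,
    poses: dict[int, JointTrajectory],
    noise: NoiseConfig,
    side: str = "left",
    quasi_static: bool = True,
) -> dict[int, SensorSet]:
    """Render every calibration pose into a sensor recording."""
    return {
        pose: SensorSet(
            streams=_render_streams(chain, traj, side, noise, quasi_static, 1000 + pose),
            side=side,
        )
        for pose, traj in poses.items()
    }


def render_forces(
    truth: GroundTruth,
    noise: NoiseConfig,
    rate: float = 100.0,
    stream_key: int = 0,
) -> dict[str, ForceChannel]:
    """Fingertip force channels: smooth rise at grasp, mass-scaled plateau,
    decay whose minimum falls exactly at release."""
    ev = truth.events
    t = np.arange(truth.trajectory.t[0], truth.trajectory.t[-1] + 1e-9, 1.0 / rate)
    plateau = 0.5 + 2.5 * truth.condition.mass_kg
    scale = {"thumb": 0.8, "index": 1.0, "middle": 0.9}
    out = {}
    for finger in FINGERS:
        p = plateau * scale[finger]
        knots = [
            (t[0], 0.0),
            (ev.t_grasp, 0.0),
            (ev.t_grasp + 0.12, p),
            (ev.t_release - 0.25, p),
            (ev.t_release, -0.2 * scale[finger]),
            (ev.t_release + 0.15, 0.0),
            (t[-1], 0.0),
        ]
        f = minimum_jerk_series(t, knots)
        if noise.force_noise_sd:
            rng = noise.stream_rng(finger, stream_key)
            f = f + rng.normal(0.0, noise.force_noise_sd, f.shape)
        out[finger] = ForceChannel(finger=finger, t=t, force=f)
    return out


def render_box_recording(noise: NoiseConfig, duration: float = 2.0, rate: float = 100.0) -> dict[str, dict[str, ImuStream]]:
    """Six-orientation static box recording for every sensor (bias estimation).

    Returns site -> orientation label -> stream; each segment is `duration`
    seconds with one sensor axis aligned to +/- gravity.
    """
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    faces = {
        "+x": Rotation.from_euler("y", -90, degrees=True),
        "-x": Rotation.from_euler("y", 90, degrees=True),
        "+y": Rotation.from_euler("x", 90, degrees=True),
        "-y": Rotation.from_euler("x", -90, degrees=True),
        "+z": Rotation.identity(),
        "-z": Rotation.from_euler("y", 180, degrees=True),
    }
    out: dict[str, dict[str, ImuStream]] = {}
    for site in SENSOR_SITES:
        gb = noise.gyro_bias(site)
        ab = noise.accel_bias(site)
        rng = noise.stream_rng(site, 901)
        segs = {}
        for label, r in faces.items():
            accel = np.broadcast_to(r.inv().apply(GRAVITY_UP), (n, 3)) + ab
            gyro = np.broadcast_to(gb, (n, 3)).copy()
            if noise.accel_noise_sd:
                accel = accel + rng.normal(0.0, noise.accel_noise_sd, (n, 3))
            if noise.gyro_noise_sd:
                gyro = gyro + rng.normal(0.0, noise.gyro_noise_sd, (n, 3))
            segs[label] = ImuStream(
                site=site, t_accel=t, accel=np.asarray(accel), t_gyro=t, gyro=gyro,
                accel_rate=rate, gyro_rate=rate,
            )
        out[site] = segs
    return out


# ---------------------------------------------------------------------------
# Calibration-session scripting
# ---------------------------------------------------------------------------

def _static_traj(duration: float, rate: float, **dofs: float) -> JointTrajectory:
    t = np.arange(int(duration * rate) + 1) / rate
    return JointTrajectory(
        t=t, angles={k: np.full_like(t, float(dofs.get(k, 0.0))) for k in DOF_NAMES}
    )


def script_calibration_session(
    side: str = "left", rate: float = 200.0, static_duration: float = 5.0
) -> dict[int, JointTrajectory]:
    """The ten-pose segment-calibration protocol as joint trajectories.

    Poses 1-5, 7 and 9 are static (>= 5 s); 6, 8 and 10 are movements
    (forearm pronation sweep, shoulder abduction sweep realising the
    upper-arm z rotation, and hip flexion to 60 deg).  Pose angles are chosen
    so that, with the side-specific protocol signs, gravity and the rotation
    axes measure the intended anatomical axes on either arm.
    """
    side_factor(side)  # validate
    poses: dict[int, JointTrajectory] = {}
    poses[1] = _static_traj(static_duration, rate, elbow_flexext=90.0)
    poses[2] = _static_traj(static_duration, rate, elbow_flexext=90.0, forearm_prosup=90.0)
    poses[3] = _static_traj(static_duration, rate, elbow_flexext=90.0)
    poses[4] = _static_traj(static_duration, rate, elbow_flexext=90.0, forearm_prosup=-90.0)
    poses[5] = _static_traj(static_duration, rate, elbow_flexext=90.0)
    # pose 6: supination-to-pronation sweep in 90 deg elbow flexion
    t6 = np.arange(int(6.0 * rate) + 1) / rate
    poses[6] = JointTrajectory(
        t=t6,
        angles={
            "elbow_flexext": np.full_like(t6, 90.0),
            "forearm_prosup": minimum_jerk_series(t6, [(0.5, 60.0), (5.5, -60.0)]),
        },
    )
    poses[7] = _static_traj(static_duration, rate, elbow_flexext=90.0)
    t8 = np.arange(int(6.0 * rate) + 1) / rate
    poses[8] = JointTrajectory(
        t=t8, angles={"shoulder_abdadd": minimum_jerk_series(t8, [(0.5, 0.0), (5.5, 60.0)])}
    )
    poses[9] = _static_traj(static_duration, rate)
    t10 = np.arange(int(5.0 * rate) + 1) / rate
    poses[10] = JointTrajectory(
        t=t10, angles={"trunk_flexion": minimum_jerk_series(t10, [(0.5, 0.0), (4.5, 60.0)])}
    )
    return poses


# ---------------------------------------------------------------------------
# Reach-trial scripting
# ---------------------------------------------------------------------------

@dataclass
class PhaseTiming:
    reach: float
    displacement: float
    return_: float
    lead_in: float = 2.4  # neutral capture + posture setup before movement
    lead_out: float = 1.2

    def __post_init__(self) -> None:
        if min(self.reach, self.displacement, self.return_) <= 0:
            raise ValueError("phase durations must be positive")

    @classmethod
    def for_arm(cls, arm: str) -> "PhaseTiming":
        # movement times: affected 4.9 s, non-affected 2.8 s
        return cls(1.575, 1.75, 1.575) if arm == "AF" else cls(0.9, 1.0, 0.9)


# per-trial scatter of the metric targets, degrees (generator conditions)
TRIAL_JITTER_SD = {"trunk_comp": 1.0, "elbow_rom": 4.0, "wrist_rom": 2.5, "finger_rom": 6.0}
# between-subject scatter used by cohort simulation
SUBJECT_SD = {"trunk_comp": 0.8, "elbow_rom": 3.0, "wrist_rom": 2.0, "finger_rom": 5.0}

_ARM_EFFECT = {"trunk_comp": 0.6, "elbow_rom": -4.95, "wrist_rom": 4.1, "finger_rom": 11.25}
_HEIGHT_EFFECT = {"trunk_comp": 0.7, "elbow_rom": 12.05, "wrist_rom": 1.6, "finger_rom": 6.15}
_BLOCK_EFFECT_TRUNK = {"BL": -0.93, "BW": -0.43, "BH": 1.37}
_GRAND_MEAN = {"trunk_comp": 8.8, "elbow_rom": 49.25, "wrist_rom": 25.3, "finger_rom": 88.35}


def condition_metric_means(condition: TrialCondition) -> dict[str, float]:
    """Displacement-phase metric targets (deg) for one task condition.

    Additive arm/height/weight model whose cell means reproduce the reported
    group means (e.g. elbow flexion-extension 44.3 deg affected vs 54.2 deg
    non-affected; 61.3 deg top vs 37.2 deg table targets; trunk compensation
    10.2 deg for the heavy vs 7.9 deg for the light block).
    """
    sa = 1.0 if condition.arm == "AF" else -1.0
    sh = 1.0 if condition.height == "Top" else -1.0
    out = {}
    for m in _GRAND_MEAN:
        v = _GRAND_MEAN[m] + sa * _ARM_EFFECT[m] + sh * _HEIGHT_EFFECT[m]
        if m == "trunk_comp":
            v += _BLOCK_EFFECT_TRUNK[condition.block]
        out[m] = v
    return out


def script_reach_trial(
    condition: TrialCondition,
    timing: PhaseTiming | None = None,
    seed: int | np.random.Generator | None = None,
    side: str = "left",
    subject_offsets: dict[str, float] | None = None,
    rate: float = 200.0,
) -> GroundTruth:
    """Script one reach-grasp-displace-return trial.

    The trial opens with a neutral standing capture and the move to the
    seated start posture (arm in 90 deg elbow flexion, hand pronated on the
    table); movement runs reach -> grasp -> displacement -> release -> return
    with minimum-jerk joint profiles.  Brisk small shoulder adjustments at
    movement onset and offset reproduce the sharp angular-velocity rise the
    threshold detector relies on.  With `seed` (or a Generator), phase
    durations and metric targets get seeded jitter; `subject_offsets` adds
    constant per-subject shifts.
    """
    timing = timing or PhaseTiming.for_arm(condition.arm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jitter = seed is not None

    tg = dict(condition_metric_means(condition))
    for m in tg:
        if subject_offsets:
            tg[m] += subject_offsets.get(m, 0.0)
        if jitter:
            tg[m] += rng.normal(0.0, TRIAL_JITTER_SD[m])
        tg[m] = max(tg[m], 2.0)

    durs = np.array([timing.reach, timing.displacement, timing.return_])
    if jitter:
        durs = durs * np.clip(rng.normal(1.0, 0.04, 3), 0.85, 1.15)
    t_start = timing.lead_in
    t_grasp = t_start + durs[0]
    t_release = t_grasp + durs[1]
    t_end = t_release + durs[2]
    total = t_end + timing.lead_out
    t = np.arange(int(total * rate) + 1) / rate

    top = condition.height == "Top"
    abducted = condition.target in ("Tab2", "Top4")
    # trunk compensation split across the three trunk angles (3-4-5-like mix)
    tc = tg["trunk_comp"]
    trunk_split = {"trunk_flexion": 0.8 * tc, "trunk_lateral": 0.48 * tc, "trunk_torsion": 0.36 * tc}
    e_release = 8.0
    e_grasp = e_release + tg["elbow_rom"]
    sh_grasp, sh_release = (45.0, 70.0) if top else (28.0, 38.0)
    ab_grasp, ab_release = (22.0, 25.0) if abducted else (6.0, 8.0)
    grip = 70.0
    thumb_rom = 30.0 + (rng.normal(0.0, 3.0) if jitter else 0.0)
    fr_index = tg["finger_rom"] + (rng.normal(0.0, 2.0) if jitter else 0.0)
    fr_middle = 2.0 * tg["finger_rom"] - fr_index  # mean stays on target

    # posture setup: neutral hold, transition, pre-movement hold
    setup_t, setup_end = 0.8, 1.8

    def script(start_value: float, knots: list[tuple[float, float]], neutral: float = 0.0):
        base = [(0.0, neutral), (setup_t, neutral), (setup_end, start_value), (t_start, start_value)]
        return minimum_jerk_series(t, base + knots)

    angles = {
        "trunk_flexion": script(0.0, [(t_grasp, 0.0), (t_release, trunk_split["trunk_flexion"]), (t_end, 0.0)]),
        "trunk_lateral": script(0.0, [(t_grasp, 0.0), (t_release, trunk_split["trunk_lateral"]), (t_end, 0.0)]),
        "trunk_torsion": script(0.0, [(t_grasp, 0.0), (t_release, trunk_split["trunk_torsion"]), (t_end, 0.0)]),
        "shoulder_flexext": script(
            5.0,
            [
                (t_start + 0.18, 9.5),
                (t_grasp, sh_grasp),
                (t_release, sh_release),
                (t_end - 0.18, 8.0),
                (t_end, 5.0),
            ],
        ),
        "shoulder_abdadd": script(0.0, [(t_grasp, ab_grasp), (t_release, ab_release), (t_end, 0.0)]),
        "elbow_flexext": script(
            90.0, [(t_grasp, e_grasp), (t_release, e_release), (t_end, 90.0)]
        ),
        "forearm_prosup": script(
            -60.0, [(t_grasp, -20.0), (t_release, -28.0), (t_end, -60.0)]
        ),
        "wrist_flexext": script(
            5.0, [(t_grasp, 8.0), (t_release, 8.0 + tg["wrist_rom"]), (t_end, 5.0)]
        ),
        "thumb_flexext": script(
            10.0,
            [
                (t_start + 0.6 * durs[0], 0.0),
                (t_grasp, 45.0),
                (t_release - 0.3 * durs[1], 45.0),
                (t_release, 45.0 - thumb_rom),
                (t_end, 10.0),
            ],
        ),
    }
    for name, rom in (("index_flexext", fr_index), ("middle_flexext", fr_middle)):
        angles[name] = script(
            10.0,
            [
                (t_start + 0.6 * durs[0], -5.0),
                (t_grasp, grip),
                (t_release - 0.3 * durs[1], grip),
                (t_release, grip - rom),
                (t_end, 10.0),
            ],
        )

    traj = JointTrajectory(t=t, angles=angles)
    events = PhaseEvents(
        t_start=t_start, t_grasp=t_grasp, t_release=t_release, t_end=t_end, method="manual"
    )
    tg.update(thumb_rom=thumb_rom, index_rom=fr_index, middle_rom=fr_middle,
              movement_time=float(t_end - t_start))
    return GroundTruth(
        trajectory=traj,
        events=events,
        condition=condition,
        side=side,
        analysis_start=setup_end + 0.2,
        targets=tg,
    )
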