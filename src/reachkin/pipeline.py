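"""End-to-end orchestration: simulate -> calibrate -> reconstruct -> segment
-> metrics -> statistics.

A :class:`SimulatedSubject` bundles everything the study protocol produces
before the first trial: the subject's kinematic chain (with randomised sensor
mountings), the sensor-noise model, the box-calibration biases and the
segment-calibration result.  :func:`process_trial` then mirrors the analysis
of one recorded trial, and :func:`run_study` loops over the 12 task
conditions x 3 repetitions of one tested arm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import CalibrationResult, calibrate_session
from .conventions import (
    BLOCKS,
    LOWPASS_CUTOFF,
    MOVEMENT_THRESHOLD,
    PROCESSING_RATE,
    REPETITIONS,
    SENSOR_SITES,
    SITE_SEGMENT,
    STATIC_GYRO_THRESHOLD,
    TARGETS,
)
from .core_io import SensorBias, SensorSet, TrialCondition, estimate_static_bias, preprocess_stream
from .kinematics import JointAngleSeries, joint_angles_from_segments
from .metrics_stats import TrialMetrics, compute_trial_metrics, metrics_table
from .orientation import FusionParams, OrientationSeries, estimate_orientation
from .segmentation import PhaseDurations, PhaseEvents, segment_trial
from .synthetic import (
    ChainModel,
    GroundTruth,
    NoiseConfig,
    render_box_recording,
    render_calibration_session,
    render_imu,
    script_calibration_session,
    script_reach_trial,
    segment_orientations,
)


@dataclass
class PipelineConfig:
    """Stage parameters; the defaults are the study's stated constants."""

    cutoff_hz: float = LOWPASS_CUTOFF
    rate_hz: float = PROCESSING_RATE
    beta: float = 0.1
    beta_static: float = 2.0
    zupt_threshold: float = STATIC_GYRO_THRESHOLD
    movement_threshold: float = MOVEMENT_THRESHOLD
    debounce_s: float = 0.1
    neutral_window: tuple[float, float] = (0.15, 0.7)
    quasi_static: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_hz >= self.rate_hz / 2:
            raise ValueError(
                f"filter cutoff {self.cutoff_hz} Hz must be below the Nyquist rate "
                f"({self.rate_hz / 2} Hz)"
            )
        if self.movement_threshold <= 0 or self.zupt_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def fusion_params(self, q0: np.ndarray) -> FusionParams:
        return FusionParams(
            beta=self.beta, beta_static=self.beta_static, zupt_threshold=self.zupt_threshold, q0=q0
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedSubject:
    subject_id: str
    side: str
    chain: ChainModel
    noise: NoiseConfig
    biases: dict[str, SensorBias]
    calibration: CalibrationResult
    subject_offsets: dict[str, float] = field(default_factory=dict)


def make_subject(
    seed: int,
    side: str = "left",
    subject_id: str = "S01",
    noise: NoiseConfig | None = None,
    config: PipelineConfig | None = None,
    chain: ChainModel | None = None,
    random_mountings: bool = True,
    subject_offsets: dict[str, float] | None = None,
) -> SimulatedSubject:
    """Simulate a subject's set-up: mountings, box calibration, segment calibration."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7]))
    if chain is None:
        chain = ChainModel()
        if random_mountings:
            chain = chain.with_random_mountings(rng)
    noise = noise or NoiseConfig(seed=seed & 0x7FFFFFFF)
    box = render_box_recording(noise)
    biases = {site: estimate_static_bias(box[site]) for site in SENSOR_SITES}
    poses = script_calibration_session(side)
    rendered = render_calibration_session(chain, poses, noise, side, quasi_static=config.quasi_static)
    prepped = {
        pose: sset.map_streams(
            lambda st: preprocess_stream(st, config.cutoff_hz, config.rate_hz, biases[st.site])
        )
        for pose, sset in rendered.items()
    }
    calibration = calibrate_session(prepped, side)
    return SimulatedSubject(
        subject_id=subject_id,
        side=side,
        chain=chain,
        noise=noise,
        biases=biases,
        calibration=calibration,
        subject_offsets=subject_offsets or {},
    )


def preprocess_set(sset: SensorSet, config: PipelineConfig, biases: dict[str, SensorBias] | None) -> SensorSet:
    return sset.map_streams(
        lambda st: preprocess_stream(
            st, config.cutoff_hz, config.rate_hz, biases[st.site] if biases else None
        )
    )


def estimate_orientations(
    sset: SensorSet, calibration: CalibrationResult, config: PipelineConfig
) -> dict[str, OrientationSeries]:
    """Per-sensor global-frame orientation, initialised from the calibration."""
    out = {}
    for site, stream in sset.streams.items():
        q0 = calibration.global_frame.initial_orientations[site]
        out[site] = estimate_orientation(stream, config.fusion_params(q0))
    return out


def segment_rotations(
    orientations: dict[str, OrientationSeries], calibration: CalibrationResult
) -> tuple[np.ndarray, dict[str, Rotation]]:
    """Apply the sensor-to-segment frames: R_segment = R_sensor R_s2s^T."""
    t = orientations["sternum"].t
    seg = {}
    for site, osr in orientations.items():
        segment = SITE_SEGMENT[site]
        if segment == "trunk" and site != "sternum":
            continue  # the sternum sensor defines the trunk
        seg[segment] = osr.as_rotation() * calibration.frames[site].rotation.inv()
    return t, seg


def reconstruct_trial(
    sset: SensorSet,
    calibration: CalibrationResult,
    config: PipelineConfig | None = None,
    biases: dict[str, SensorBias] | None = None,
    preprocessed: bool = False,
) -> JointAngleSeries:
    """Joint angles of one trial from its (raw or preprocessed) sensor set."""
    config = config or PipelineConfig()
    prepped = sset if preprocessed else preprocess_set(sset, config, biases)
    orients = estimate_orientations(prepped, calibration, config)
    t, seg = segment_rotations(orients, calibration)
    return joint_angles_from_segments(
        t, seg, side=calibration.side, neutral_window=config.neutral_window
    )


@dataclass
class ProcessedTrial:
    condition: TrialCondition
    angles: JointAngleSeries
    events: PhaseEvents
    durations: PhaseDurations
    metrics: TrialMetrics
    truth: GroundTruth | None = None


def process_trial(
    sset: SensorSet,
    calibration: CalibrationResult,
    config: PipelineConfig | None = None,
    biases: dict[str, SensorBias] | None = None,
    subject_id: str = "S01",
    truth: GroundTruth | None = None,
) -> ProcessedTrial:
    """Reconstruct, segment and score one trial."""
    config = config or PipelineConfig()
    prepped = preprocess_set(sset, config, biases)
    angles = reconstruct_trial(prepped, calibration, config, preprocessed=True)
    events, durations = segment_trial(
        prepped,
        angles,
        threshold=config.movement_threshold,
        debounce=config.debounce_s,
        search_start=sset.analysis_start,
    )
    metrics = compute_trial_metrics(
        angles, events, sset.condition, durations, subject=subject_id
    )
    return ProcessedTrial(
        condition=sset.condition,
        angles=angles,
        events=events,
        durations=durations,
        metrics=metrics,
        truth=truth,
    )


def simulate_trial(
    subject: SimulatedSubject,
    condition: TrialCondition,
    trial_seed: int,
    config: PipelineConfig | None = None,
) -> tuple[GroundTruth, SensorSet]:
    """Script and render one trial of a simulated subject."""
    config = config or PipelineConfig()
    truth = script_reach_trial(
        condition,
        seed=trial_seed,
        side=subject.side,
        subject_offsets=subject.subject_offsets,
    )
    sset = render_imu(
        subject.chain, truth, subject.noise, quasi_static=config.quasi_static, stream_key=trial_seed
    )
    return truth, sset


def default_conditions(arm: str) -> list[TrialCondition]:
    """The 12 task conditions x 3 repetitions of one tested arm."""
    return [
        TrialCondition(arm=arm, block=b, target=tgt, repetition=r)
        for b in BLOCKS
        for tgt in TARGETS
        for r in REPETITIONS
    ]


def _trial_seed(seed: int, condition: TrialCondition) -> int:
    key = (
        BLOCKS.index(condition.block) * 16
        + TARGETS.index(condition.target) * 4
        + condition.repetition
        + (1000 if condition.arm == "AF" else 0)
    )
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, 11, key]).generate_state(1)[0] & 0x7FFFFFFF)


def run_study(
    subject: SimulatedSubject,
    arm: str,
    config: PipelineConfig | None = None,
    conditions: list[TrialCondition] | None = None,
) -> list[ProcessedTrial]:
    """Simulate and fully process every trial of one tested arm."""
    config = config or PipelineConfig()
    conditions = conditions or default_conditions(arm)
    out = []
    for cond in conditions:
        truth, sset = simulate_trial(subject, cond, _trial_seed(config.seed, cond), config)
        out.append(
            process_trial(sset, subject.calibration, config, subject.biases, subject.subject_id, truth)
        )
    return out


# ---------------------------------------------------------------------------
# Recovery diagnostics (used by the validation suite and acceptance script)
# ---------------------------------------------------------------------------

def orientation_errors_deg(
    subject: SimulatedSubject,
    truth: GroundTruth,
    sset: SensorSet,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Per-sensor RMS angle between estimated and true orientation, degrees."""
    config = config or PipelineConfig()
    prepped = preprocess_set(sset, config, subject.biases)
    orients = estimate_orientations(prepped, subject.calibration, config)
    seg_true = segment_orientations(truth.trajectory, truth.side)
    out = {}
    for site, osr in orients.items():
        r_true_full = seg_true[SITE_SEGMENT[site]] * subject.chain.mountings[site]
        idx = np.clip(
            np.round((osr.t - truth.trajectory.t[0]) * truth.trajectory.rate).astype(int),
            0,
            len(truth.trajectory.t) - 1,
        )
        err = (osr.as_rotation().inv() * r_true_full[idx]).magnitude()
        out[site] = float(np.degrees(np.sqrt(np.mean(err**2))))
    return out


def joint_angle_rmse_deg(
    angles: JointAngleSeries, truth: GroundTruth, window: tuple[float, float] | None = None
) -> dict[str, float]:
    """Per-DOF RMSE between reconstructed and scripted joint angles."""
    traj = truth.trajectory
    t0, t1 = window or (truth.events.t_start, truth.events.t_end)
    m = (angles.t >= t0) & (angles.t < t1)
    idx = np.clip(np.round((angles.t[m] - traj.t[0]) * traj.rate).astype(int), 0, len(traj.t) - 1)
    out = {}
    for name, est in angles.angles.items():
        out[name] = float(np.sqrt(np.mean((est[m] - traj.angles[name][idx]) ** 2)))
    return out


def study_metrics_frame(trials: list[ProcessedTrial]):
    return metrics_table([tr.metrics for tr in trials])
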