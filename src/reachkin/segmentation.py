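"""Trial phase segmentation: reach / displacement / return.

Movement start and end come from a threshold detector on the upper-arm
angular-velocity norm (0.1 rad/s, 100 ms debounce).  Grasp and release come
from the fingertip force channels when a usable force profile exists: grasp is
the first sustained rise of any channel above its baseline, release the global
force minimum after the grip plateau.  When no force profile qualifies, a
kinematic fallback uses the finger-closure velocity zero crossing (grasp) and
the point of maximum elbow extension (release).  Every sample in
[t_start, t_end) belongs to exactly one phase (half-open intervals), so there
is no dead time between phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conventions import MOVEMENT_THRESHOLD
from .core_io import ForceChannel, SensorSet


class NoMovementError(ValueError):
    """The angular-velocity norm never exceeds the movement threshold."""


class DetectionError(ValueError):
    """Grasp/release could not be located in the available signals."""


@dataclass
class PhaseEvents:
    t_start: float
    t_grasp: float
    t_release: float
    t_end: float
    method: str = "manual"  # force | kinematic | manual
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_grasp < self.t_release < self.t_end):
            raise ValueError(
                "events must satisfy t_start < t_grasp < t_release < t_end, got "
                f"({self.t_start:.3f}, {self.t_grasp:.3f}, {self.t_release:.3f}, {self.t_end:.3f})"
            )
        if self.method not in ("force", "kinematic", "manual"):
            raise ValueError(f"unknown method {self.method!r}")

    def as_dict(self) -> dict:
        return {
            "t_start": self.t_start,
            "t_grasp": self.t_grasp,
            "t_release": self.t_release,
            "t_end": self.t_end,
            "method": self.method,
            "quality_ok": self.quality_ok,
        }


@dataclass
class PhaseDurations:
    reach: float
    displacement: float
    return_: float
    movement_time: float

    def __post_init__(self) -> None:
        if min(self.reach, self.displacement, self.return_) <= 0:
            raise ValueError("phase durations must be positive")
        if abs(self.movement_time - (self.reach + self.displacement + self.return_)) > 1e-9:
            raise ValueError("movement_time must equal the summed phase durations")

    @classmethod
    def from_events(cls, ev: PhaseEvents) -> "PhaseDurations":
        return cls(
            reach=ev.t_grasp - ev.t_start,
            displacement=ev.t_release - ev.t_grasp,
            return_=ev.t_end - ev.t_release,
            movement_time=ev.t_end - ev.t_start,
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i, j) index runs of consecutive True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_movement_bounds(
    t: np.ndarray,
    gyro_norm: np.ndarray,
    threshold: float = MOVEMENT_THRESHOLD,
    debounce: float = 0.1,
) -> tuple[float, float]:
    """Movement start/end from the upper-arm angular-velocity norm.

    t_start is the first sample of the first supra-threshold run lasting at
    least `debounce` seconds; t_end the last sample of the last such run.
    """
    t = np.asarray(t, dtype=float)
    gyro_norm = np.asarray(gyro_norm, dtype=float)
    if len(t) < 2 or t[-1] - t[0] < 1.0:
        raise ValueError("need at least 1 s of signal")
    runs = [(i, j) for i, j in _runs(gyro_norm > threshold) if t[j - 1] - t[i] >= debounce]
    if not runs:
        raise NoMovementError(f"angular-velocity norm never sustained above {threshold} rad/s")
    return float(t[runs[0][0]]), float(t[runs[-1][1] - 1])


def detect_grasp_release_force(
    forces: dict[str, ForceChannel],
    bounds: tuple[float, float],
    rise_sds: float = 3.0,
    sustain: float = 0.05,
    baseline_window: float = 0.5,
) -> tuple[float, float] | None:
    """Grasp and release from the fingertip force channels.

    Grasp: earliest time any channel exceeds its baseline mean plus
    ``rise_sds`` baseline standard deviations (with a floor of 2% of the
    channel's range, so noise-free profiles are still detectable), sustained
    for `sustain` seconds.  Release: global minimum of the summed force after
    the last plateau (the last supra-threshold sample) within bounds.

    Returns None when no channel meets the rise criterion, signalling the
    caller to fall back to the kinematic method.
    """
    t0, t1 = bounds
    grasp_candidates = []
    sum_t = None
    sum_f = None
    for fc in forces.values():
        m = (fc.t >= t0) & (fc.t < t1)
        t, f = fc.t[m], fc.force[m]
        if len(t) < 3:
            continue
        base = f[t < t0 + baseline_window]
        if len(base) < 2:
            continue
        rng = float(f.max() - base.mean())
        if rng <= 0:
            continue
        thr = base.mean() + max(rise_sds * base.std(), 0.02 * rng)
        above = f > thr
        dt = float(np.median(np.diff(t)))
        need = max(1, int(round(sustain / dt)))
        runs = [(i, j) for i, j in _runs(above) if j - i >= need]
        if not runs:
            continue
        grasp_candidates.append((float(t[runs[0][0]]), t, f, thr, float(t[runs[-1][1] - 1])))
        if sum_t is None:
            sum_t, sum_f = t, f.copy()
        else:
            sum_f = sum_f + np.interp(sum_t, t, f)
    if not grasp_candidates:
        return None
    t_grasp = min(c[0] for c in grasp_candidates)
    # release: minimum of the (lightly smoothed) summed force after the last
    # sustained supra-threshold run, within a bounded search window
    t_plateau_end = max(c[4] for c in grasp_candidates)
    last_plateau = int(np.searchsorted(sum_t, t_plateau_end))
    last_plateau = min(last_plateau, len(sum_t) - 1)
    dt = float(np.median(np.diff(sum_t)))
    k = max(1, int(round(0.05 / dt)) | 1)
    smoothed = np.convolve(sum_f, np.ones(k) / k, mode="same")
    stop = min(len(sum_t), last_plateau + int(round(1.0 / dt)))
    rel_idx = last_plateau + int(np.argmin(smoothed[last_plateau:stop]))
    t_release = float(sum_t[rel_idx])
    if not t_grasp < t_release:
        return None
    return t_grasp, t_release


def detect_grasp_release_kinematic(
    angles,
    bounds: tuple[float, float],
    vel_eps_deg_s: float = 2.0,
    confirm_window: float = 0.25,
) -> tuple[float, float, bool]:
    """Grasp and release from the joint-angle profiles.

    Grasp: after the fastest finger-closing instant, the first time the mean
    index/middle flexion velocity falls back below a small threshold (the
    closing-to-hold transition).  Release: maximum elbow extension (minimum
    elbow angle) inside the bounds, confirmed when a finger-extension onset
    lies within `confirm_window` seconds of it; failed confirmation lowers the
    quality flag but the elbow-based time is still returned.
    """
    t = np.asarray(angles.t, dtype=float)
    m = (t >= bounds[0]) & (t < bounds[1])
    t = t[m]
    if len(t) < 5:
        raise DetectionError("too few samples inside bounds")
    finger = 0.5 * (np.asarray(angles.angles["index_flexext"])[m] + np.asarray(angles.angles["middle_flexext"])[m])
    elbow = np.asarray(angles.angles["elbow_flexext"])[m]
    vel = np.gradient(finger, t)
    if vel.max() < vel_eps_deg_s:
        raise DetectionError("no finger closing detected (monotone or constant finger angle)")
    peak = int(np.argmax(vel))
    after = np.where(vel[peak:] < vel_eps_deg_s)[0]
    if len(after) == 0:
        raise DetectionError("finger closing never settles into a hold")
    gi = peak + int(after[0])
    t_grasp = float(t[gi])
    # release: maximum elbow extension after grasp.  The elbow profile is
    # nearly flat around its extremum, so the raw argmin jitters; take the
    # midpoint of the contiguous near-minimum valley instead.
    post = elbow[gi + 1 :]
    emin = float(post.min())
    lo = gi + 1 + int(np.argmin(post))
    hi = lo
    while lo > gi + 1 and elbow[lo - 1] <= emin + 0.25:
        lo -= 1
    while hi < len(elbow) - 1 and elbow[hi + 1] <= emin + 0.25:
        hi += 1
    ri = (lo + hi) // 2
    t_release = float(t[ri])
    # confirmation: finger extension onset (velocity strongly negative) near release
    ext = vel < -vel_eps_deg_s
    ok = bool(ext.any() and np.min(np.abs(t[ext] - t_release)) <= confirm_window)
    return t_grasp, t_release, ok


def segment_trial(
    sensor_set: SensorSet,
    angles,
    threshold: float = MOVEMENT_THRESHOLD,
    debounce: float = 0.1,
    search_start: float | None = None,
) -> tuple[PhaseEvents, PhaseDurations]:
    """Full segmentation: bounds, then force-based events with kinematic fallback.

    `search_start` restricts the analysis to t >= search_start (e.g. to skip
    the pre-trial posture setup recorded in the same stream).
    """
    ua = sensor_set.streams["upper_arm"]
    t = ua.t
    norm = np.linalg.norm(ua.gyro, axis=1)
    if search_start is None:
        search_start = getattr(sensor_set, "analysis_start", 0.0) or 0.0
    m = t >= search_start
    t_start, t_end = detect_movement_bounds(t[m], norm[m], threshold, debounce)
    bounds = (t_start, t_end)
    got = detect_grasp_release_force(sensor_set.forces, bounds) if sensor_set.forces else None
    quality_ok = True
    if got is not None:
        t_grasp, t_release = got
        method = "force"
    else:
        t_grasp, t_release, quality_ok = detect_grasp_release_kinematic(angles, bounds)
        method = "kinematic"
    events = PhaseEvents(
        t_start=t_start,
        t_grasp=t_grasp,
        t_release=t_release,
        t_end=t_end,
        method=method,
        quality_ok=quality_ok,
    )
    return events, PhaseDurations.from_events(events)
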