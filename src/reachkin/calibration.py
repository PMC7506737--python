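"""Sensor-to-segment calibration and global-frame definition.

The segment frames come from a ten-pose protocol (eight static postures, two
dynamic movements).  In a static posture the accelerometer's gravity reading
gives the sensor-frame direction of one anatomical axis; in a dynamic
movement the dominant rotation axis of the gyroscope gives another.  Each
segment frame is assembled from two such labeled axes — the better-observed
one kept exact, the second re-orthogonalised against it — and the third axis
follows by cross product in right-handed x, y, z label order.

The last two poses (standing straight; bending forward by hip flexion) define
the common global frame: gravity gives the vertical axis, the hip-flexion
rotation axis the mediolateral axis, for every sensor simultaneously, and the
per-sensor initial orientations at the neutral pose follow.

Axis signs per tested side are the protocol table in
:data:`reachkin.conventions.CALIBRATION_PROTOCOL`.  Note the upper-arm row
(pose 7) carries a negative sign for both sides: with the anatomical x-axis
pointing distally, the hanging upper arm measures the "up" direction as -x on
either arm, so the equal signs are geometrically correct rather than a
protocol asymmetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .conventions import (
    CALIBRATION_PROTOCOL,
    SEGMENT_AXIS_PLAN,
    SENSOR_SITES,
    SIDES,
    SITE_SEGMENT,
    STATIC_GYRO_THRESHOLD,
)
from .core_io import CalibrationError, ImuStream, SensorSet
from .orientation import detect_static

_AXIS_ORDER = ("x", "y", "z")


@dataclass
class CalibrationProtocol:
    """The ten-row pose table: (pose id, static/dynamic, per-site axis signs)."""

    rows: dict = field(default_factory=lambda: dict(CALIBRATION_PROTOCOL))

    def __post_init__(self) -> None:
        if len(self.rows) != 10:
            raise ValueError("protocol must have exactly 10 rows")
        for pose, (kind, items) in self.rows.items():
            if kind not in ("static", "dynamic"):
                raise ValueError(f"pose {pose}: kind must be static or dynamic")
            for site, axis, sl, sr in items:
                if site not in SENSOR_SITES or axis not in _AXIS_ORDER or {sl, sr} - {1, -1}:
                    raise ValueError(f"pose {pose}: malformed row {(site, axis, sl, sr)}")

    def sign(self, pose: int, site: str, side: str) -> int:
        for s, axis, sl, sr in self.rows[pose][1]:
            if s == site:
                return sl if side == "left" else sr
        raise KeyError((pose, site))


@dataclass
class AnatomicalFrame:
    """Sensor-to-segment rotation: v_segment = R_s2s @ v_sensor.

    Rows of R_s2s are the segment's anatomical axes in sensor coordinates.
    axis_labels records which two axes were measured and which was crossed.
    """

    segment: str
    R_s2s: np.ndarray
    axis_labels: tuple[str, str, str]  # (primary, secondary, crossed)

    def __post_init__(self) -> None:
        self.R_s2s = np.asarray(self.R_s2s, dtype=float)
        if self.R_s2s.shape != (3, 3):
            raise ValueError("R_s2s must be 3x3")
        if np.max(np.abs(self.R_s2s @ self.R_s2s.T - np.eye(3))) > 1e-6:
            raise CalibrationError(f"{self.segment}: R_s2s not orthonormal")
        if np.linalg.det(self.R_s2s) < 0:
            raise CalibrationError(f"{self.segment}: R_s2s is a reflection")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_matrix(self.R_s2s)


@dataclass
class GlobalFrame:
    """Common frame for all sensors: Z up, Y mediolateral, X = Y x Z anterior."""

    vertical: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    mediolateral: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    anterior: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    initial_orientations: dict[str, np.ndarray] = field(default_factory=dict)  # site -> quat wxyz

    def __post_init__(self) -> None:
        axes = np.column_stack([self.anterior, self.mediolateral, self.vertical])
        if np.max(np.abs(axes @ axes.T - np.eye(3))) > 1e-6 or np.linalg.det(axes) < 0:
            raise CalibrationError("global axes must form a right-handed orthonormal triad")

    def initial_rotation(self, site: str) -> Rotation:
        q = self.initial_orientations[site]
        return Rotation.from_quat(np.roll(q, -1))  # stored scalar-first


def static_window(stream: ImuStream, keep: float = 3.0) -> ImuStream:
    """Central `keep` seconds of a static pose (trims don/settle transients)."""
    t0, t1 = stream.span
    if t1 - t0 <= keep:
        return stream
    mid = 0.5 * (t0 + t1)
    return stream.slice(mid - keep / 2, mid + keep / 2 + 1e-9)


def axis_from_static(window: ImuStream, sign: int) -> np.ndarray:
    """Anatomical axis in sensor coordinates from a static pose.

    The normalised mean accelerometer reading is the sensor-frame "up"
    direction; `sign` orients it along the anatomical axis.
    """
    if len(window.t_accel) < 2 or (window.t_accel[-1] - window.t_accel[0]) < 1.0:
        raise CalibrationError("static window shorter than 1 s")
    frac = float(np.mean(detect_static(window.gyro, STATIC_GYRO_THRESHOLD)))
    if frac < 0.9:
        raise CalibrationError(f"window not static ({frac:.0%} of samples below threshold)")
    v = window.accel.mean(axis=0)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise CalibrationError("zero mean acceleration in static window")
    return sign * v / n


def axis_from_dynamic(
    window: ImuStream,
    sign: int,
    min_sweep_deg: float = 45.0,
    min_eig_ratio: float = 4.0,
) -> np.ndarray:
    """Anatomical axis in sensor coordinates from a single-axis movement.

    The dominant axis is the principal eigenvector of the gyro outer-product
    sum; it is oriented so the net signed rotation about it is positive, then
    multiplied by `sign`.
    """
    w = window.gyro
    if len(w) < 3:
        raise CalibrationError("dynamic window too short")
    scatter = w.T @ w
    evals, evecs = np.linalg.eigh(scatter)
    if evals[-1] < 1e-12 or (evals[-2] > 1e-12 and evals[-1] / evals[-2] < min_eig_ratio):
        raise CalibrationError(
            f"no dominant rotation axis (eigenvalue ratio {evals[-1] / max(evals[-2], 1e-12):.2f} < {min_eig_ratio})"
        )
    axis = evecs[:, -1]
    net = np.trapezoid(w @ axis, window.t_gyro)
    if abs(np.degrees(net)) < min_sweep_deg:
        raise CalibrationError(
            f"rotation sweep {abs(np.degrees(net)):.1f} deg below the {min_sweep_deg} deg minimum"
        )
    if net < 0:
        axis = -axis
    return sign * axis


def build_segment_frame(
    segment: str,
    axis_a: tuple[str, np.ndarray],
    axis_b: tuple[str, np.ndarray],
) -> AnatomicalFrame:
    """Assemble the sensor-to-segment rotation from two labeled axes.

    axis_a is primary (kept exact, typically the gravity-derived axis);
    axis_b is re-orthogonalised against it; the third axis follows from the
    right-handed relations x = y X z, y = z X x, z = x X y.
    """
    (la, va), (lb, vb) = axis_a, axis_b
    if la == lb:
        raise ValueError(f"{segment}: two measurements of the same axis {la!r}")
    va = np.asarray(va, dtype=float) / np.linalg.norm(va)
    vb = np.asarray(vb, dtype=float) / np.linalg.norm(vb)
    if abs(float(va @ vb)) >= 0.9:
        raise CalibrationError(f"{segment}: measured axes nearly parallel (|cos| = {abs(va @ vb):.3f})")
    vb = vb - (va @ vb) * va
    vb = vb / np.linalg.norm(vb)
    axes = {la: va, lb: vb}
    (lc,) = set(_AXIS_ORDER) - {la, lb}
    cross_rule = {"x": ("y", "z"), "y": ("z", "x"), "z": ("x", "y")}
    u, v = cross_rule[lc]
    axes[lc] = np.cross(axes[u], axes[v])
    R = np.stack([axes[l] for l in _AXIS_ORDER])
    return AnatomicalFrame(segment=segment, R_s2s=R, axis_labels=(la, lb, lc))


def build_global_frame(
    pose9: dict[str, ImuStream],
    pose10: dict[str, ImuStream],
) -> GlobalFrame:
    """Global frame and per-sensor initial orientations from the last two poses.

    For every sensor, the standing pose gives the vertical (gravity) axis and
    the hip-flexion movement the mediolateral axis (its dominant rotation
    axis, projected orthogonal to vertical); the anterior axis completes the
    right-handed triad and the neutral-pose orientation follows.
    """
    missing = [s for s in SENSOR_SITES if s not in pose9 or s not in pose10]
    if missing:
        raise CalibrationError(f"poses 9/10 missing for site(s): {', '.join(missing)}")
    initial = {}
    for site in SENSOR_SITES:
        up = axis_from_static(static_window(pose9[site]), +1)
        ml = axis_from_dynamic(pose10[site], +1)
        ml = ml - (ml @ up) * up
        n = np.linalg.norm(ml)
        if n < 0.1:
            raise CalibrationError(f"{site}: hip-flexion axis nearly vertical")
        ml = ml / n
        ant = np.cross(ml, up)
        # rows of R_init are the global axes in sensor coordinates
        R_init = np.stack([ant, ml, up])
        q = Rotation.from_matrix(R_init).as_quat()
        initial[site] = np.roll(q if q[3] >= 0 else -q, 1)  # scalar-first
    return GlobalFrame(initial_orientations=initial)


@dataclass
class CalibrationResult:
    side: str
    frames: dict[str, AnatomicalFrame]  # keyed by sensor site
    global_frame: GlobalFrame

    def frame_for_site(self, site: str) -> AnatomicalFrame:
        return self.frames[site]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "side": self.side,
            "frames": {
                site: {
                    "segment": f.segment,
                    "R_s2s": f.R_s2s.tolist(),
                    "axis_labels": list(f.axis_labels),
                }
                for site, f in self.frames.items()
            },
            "global_frame": {
                "vertical": self.global_frame.vertical.tolist(),
                "mediolateral": self.global_frame.mediolateral.tolist(),
                "anterior": self.global_frame.anterior.tolist(),
                "initial_orientations": {
                    k: v.tolist() for k, v in self.global_frame.initial_orientations.items()
                },
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        d = json.loads(Path(path).read_text())
        frames = {
            site: AnatomicalFrame(
                segment=f["segment"], R_s2s=np.array(f["R_s2s"]), axis_labels=tuple(f["axis_labels"])
            )
            for site, f in d["frames"].items()
        }
        gf = GlobalFrame(
            vertical=np.array(d["global_frame"]["vertical"]),
            mediolateral=np.array(d["global_frame"]["mediolateral"]),
            anterior=np.array(d["global_frame"]["anterior"]),
            initial_orientations={
                k: np.array(v) for k, v in d["global_frame"]["initial_orientations"].items()
            },
        )
        return cls(side=d["side"], frames=frames, global_frame=gf)


def calibrate_session(
    poses: dict[int, SensorSet],
    side: str,
    protocol: CalibrationProtocol | None = None,
) -> CalibrationResult:
    """Run the full protocol: per-site anatomical frames plus the global frame.

    `poses` maps pose id (1..10) to the preprocessed recording of that pose.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    protocol = protocol or CalibrationProtocol()
    missing = sorted(set(protocol.rows) - set(poses))
    if missing:
        raise CalibrationError(f"missing calibration pose(s): {missing}")
    measured: dict[str, dict[str, np.ndarray]] = {s: {} for s in SENSOR_SITES}
    for pose, (kind, items) in protocol.rows.items():
        for site, axis_label, sl, sr in items:
            sign = sl if side == "left" else sr
            stream = poses[pose].streams[site]
            if kind == "static":
                vec = axis_from_static(static_window(stream), sign)
            else:
                vec = axis_from_dynamic(stream, sign)
            measured[site][axis_label] = vec
    frames = {}
    for site in SENSOR_SITES:
        plan = SEGMENT_AXIS_PLAN[SITE_SEGMENT[site]]
        got = measured[site]
        if not set(plan).issubset(got):
            raise CalibrationError(f"{site}: protocol did not yield axes {plan}")
        frames[site] = build_segment_frame(
            SITE_SEGMENT[site], (plan[0], got[plan[0]]), (plan[1], got[plan[1]])
        )
    global_frame = build_global_frame(
        {s: poses[9].streams[s] for s in SENSOR_SITES},
        {s: poses[10].streams[s] for s in SENSOR_SITES},
    )
    return CalibrationResult(side=side, frames=frames, global_frame=global_frame)
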