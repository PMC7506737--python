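"""Sensor orientation from gyro strapdown with gravity correction and ZUPT.

Quaternions are Hamilton, scalar-first (w, x, y, z) and rotate sensor-frame
vectors into the global frame.  The Madgwick update integrates the gyroscope
quaternion derivative and descends the gradient of the gravity-alignment
objective

    f(q) = R(q)^T z_hat - a_hat,

where a_hat is the normalised accelerometer reading, so only the inclination
(never the heading) is corrected.  Zero-velocity updates freeze integration
whenever the angular-velocity norm falls below 3 deg/s: the gyro sample is
treated as zero and the corrective gain is raised, which arrests both bias
drift and noise random walk while the sensor is at rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .conventions import STATIC_GYRO_THRESHOLD
from .core_io import ImuStream


# -- quaternion helpers (scalar-first) --------------------------------------

def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def quat_to_rotation(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))  # to scalar-last


def rotation_to_quat(r: Rotation) -> np.ndarray:
    q = np.roll(r.as_quat(), 1, axis=-1)  # to scalar-first
    return np.where(q[..., :1] < 0, -q, q) if q.ndim > 1 else (-q if q[0] < 0 else q)


def quat_angle_deg(p: np.ndarray, q: np.ndarray) -> float:
    """Rotation angle between two unit quaternions, degrees."""
    d = abs(float(np.dot(p, q)))
    return float(np.degrees(2.0 * np.arccos(min(1.0, d))))


# ---------------------------------------------------------------------------

@dataclass
class FusionParams:
    """Tuning of the orientation filter.

    beta is the gradient-descent gain in rad/s during motion; beta_static is
    the raised gain applied on zero-velocity samples.  zupt_threshold is the
    angular-velocity norm below which a sample counts as static (3 deg/s).
    """

    beta: float = 0.1
    beta_static: float = 2.0
    zupt_threshold: float = STATIC_GYRO_THRESHOLD
    q0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    use_zupt: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0 or self.beta_static < 0:
            raise ValueError("beta gains must be non-negative")
        if self.zupt_threshold <= 0:
            raise ValueError("zupt_threshold must be positive")
        self.q0 = quat_normalize(np.asarray(self.q0, dtype=float))


@dataclass
class OrientationSeries:
    """Unit-quaternion trajectory of one sensor in the global frame."""

    t: np.ndarray
    q: np.ndarray  # (N, 4) scalar-first
    static_mask: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.static_mask = np.asarray(self.static_mask, dtype=bool)
        if not (len(self.t) == len(self.q) == len(self.static_mask)):
            raise ValueError("t, q and static_mask must have equal length")
        if len(self.q) and np.max(np.abs(np.linalg.norm(self.q, axis=1) - 1.0)) > 1e-6:
            raise ValueError("quaternions must be unit norm")

    def as_rotation(self) -> Rotation:
        return quat_to_rotation(self.q)


def detect_static(gyro: np.ndarray, threshold: float = STATIC_GYRO_THRESHOLD) -> np.ndarray:
    """Boolean mask, True exactly where ||omega|| < threshold (rad/s)."""
    gyro = np.asarray(gyro, dtype=float)
    if not np.all(np.isfinite(gyro)):
        raise ValueError("gyro contains non-finite samples")
    return np.linalg.norm(gyro, axis=-1) < threshold


def madgwick_step(
    q: np.ndarray,
    gyro: np.ndarray,
    accel: np.ndarray,
    beta: float,
    dt: float,
) -> np.ndarray:
    """One gradient-descent orientation update.

    Integrates q_dot = 1/2 q (x) (0, omega) and subtracts beta times the
    normalised gradient of the gravity-alignment objective, then renormalises.
    For small gravity residuals (|f| below ~6 deg of inclination error) the
    step is scaled proportionally instead of keeping the constant magnitude
    beta, which removes the limit-cycle dither of the fixed-size step around
    convergence.  A zero-norm accelerometer sample skips the correction
    (gyro-only step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    w, x, y, z = q
    gx, gy, gz = gyro
    qdot = 0.5 * np.array(
        [
            -x * gx - y * gy - z * gz,
            w * gx + y * gz - z * gy,
            w * gy - x * gz + z * gx,
            w * gz + x * gy - y * gx,
        ]
    )
    anorm = float(np.linalg.norm(accel))
    if beta > 0 and anorm > 1e-12:
        ax, ay, az = np.asarray(accel, dtype=float) / anorm
        # objective f = R(q)^T z_hat - a_hat; R(q)^T z_hat is the third row of R(q)
        f1 = 2.0 * (x * z - w * y) - ax
        f2 = 2.0 * (y * z + w * x) - ay
        f3 = 1.0 - 2.0 * (x * x + y * y) - az
        # J^T f with J the Jacobian of f wrt (w, x, y, z)
        step = np.array(
            [
                -2.0 * y * f1 + 2.0 * x * f2,
                2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3,
                -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3,
                2.0 * x * f1 + 2.0 * y * f2,
            ]
        )
        snorm = float(np.linalg.norm(step))
        if snorm > 1e-12:
            residual = float(np.sqrt(f1 * f1 + f2 * f2 + f3 * f3))
            gain = beta * min(1.0, residual / 0.1)
            qdot = qdot - gain * step / snorm
    return quat_normalize(q + qdot * dt)


def estimate_orientation(stream: ImuStream, params: FusionParams | None = None) -> OrientationSeries:
    """Run the filter over a preprocessed (filtered, de-biased, resampled) stream.

    Gyro samples are averaged over each integration interval (trapezoid) to
    avoid the half-sample lag of plain rectangular integration.  On static
    samples the gyro is zeroed and the raised gain applied (ZUPT).
    """
    params = params or FusionParams()
    t = stream.t  # raises if channels not aligned
    n = len(t)
    if n == 0:
        return OrientationSeries(t=t, q=np.empty((0, 4)), static_mask=np.empty(0, dtype=bool))
    if not (np.all(np.isfinite(stream.gyro)) and np.all(np.isfinite(stream.accel))):
        bad = int(np.argmax(~(np.isfinite(stream.gyro).all(axis=1) & np.isfinite(stream.accel).all(axis=1))))
        raise ValueError(f"{stream.site}: non-finite input at sample {bad}")
    static = detect_static(stream.gyro, params.zupt_threshold) if params.use_zupt else np.zeros(n, dtype=bool)
    q = np.empty((n, 4))
    q[0] = params.q0
    for k in range(n - 1):
        dt = t[k + 1] - t[k]
        if static[k] and params.use_zupt:
            gyro = np.zeros(3)
            beta = params.beta_static
        else:
            gyro = 0.5 * (stream.gyro[k] + stream.gyro[k + 1])
            beta = params.beta
        q[k + 1] = madgwick_step(q[k], gyro, stream.accel[k], beta, dt)
    return OrientationSeries(t=t, q=q, static_mask=static)
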