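"""Joint angles from segment orientations.

Eleven degrees of freedom are reported, all in degrees:

* trunk flexion / lateral rotation / torsion — decomposition of the sternum
  frame's displacement from the static neutral pose about its y, x and z axes
  (intrinsic y-x-z sequence, which reduces to the projected-axis definition
  for single-plane motion).
* shoulder flexion-extension — angle of the upper arm's x-axis projected into
  the sternum x-z plane, measured from the hanging (downward) direction;
  shoulder abduction-adduction — the same axis projected into the sternum
  y-z plane.
* elbow flexion-extension — angle between the upper and lower arm x-axes
  (non-negative: the generator and protocol exclude hyperextension).
* forearm pronation-supination — twist of the forearm about its own x-axis
  relative to the upper arm and the pre-trial neutral posture (swing-twist
  decomposition; supination positive).
* wrist and finger flexion-extension — angle between the proximal and distal
  x-axes, signed by the sense of rotation about the proximal segment's
  mediolateral (y) axis so flexion is positive.

Sign conventions per tested side live in :data:`reachkin.conventions.ANGLE_SIGNS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .conventions import ANGLE_SIGNS, DOF_NAMES


@dataclass
class NeutralReference:
    """Per-trial neutral-pose capture: trunk orientation and forearm twist zero."""

    trunk: Rotation
    forearm_rel_upper: Rotation


@dataclass
class JointAngleSeries:
    t: np.ndarray
    angles: dict[str, np.ndarray]
    side: str = "left"
    neutral: NeutralReference | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name, arr in self.angles.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name}: length mismatch with t")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: non-finite angles")
            self.angles[name] = arr

    def window(self, t0: float, t1: float) -> "JointAngleSeries":
        m = (self.t >= t0) & (self.t < t1)
        return JointAngleSeries(
            t=self.t[m], angles={k: v[m] for k, v in self.angles.items()}, side=self.side
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **{k: self.angles[k] for k in DOF_NAMES if k in self.angles}})


def _x_axis(r: Rotation) -> np.ndarray:
    return r.apply(np.array([1.0, 0.0, 0.0]))


def _y_axis(r: Rotation) -> np.ndarray:
    return r.apply(np.array([0.0, 1.0, 0.0]))


def trunk_angles(
    trunk: Rotation, neutral: Rotation, side: str = "left"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trunk flexion, lateral rotation and torsion relative to the neutral pose."""
    if neutral is None:
        raise ValueError("trunk angles need the neutral-pose reference")
    rel = neutral.inv() * trunk
    eul = rel.as_euler("YXZ", degrees=True)
    eul = np.atleast_2d(eul)
    signs = ANGLE_SIGNS[side]
    return (
        signs["trunk_flexion"] * eul[:, 0],
        signs["trunk_lateral"] * eul[:, 1],
        signs["trunk_torsion"] * eul[:, 2],
    )


def shoulder_angles(
    upper_arm: Rotation, trunk: Rotation, side: str = "left"
) -> tuple[np.ndarray, np.ndarray]:
    """Shoulder flexion-extension and abduction-adduction.

    The upper arm's x-axis is expressed in the sternum frame and projected
    into its x-z (flexion) and y-z (abduction) planes; angles are measured
    from the downward neutral direction.
    """
    v = trunk.inv().apply(_x_axis(upper_arm))
    v = np.atleast_2d(v)
    signs = ANGLE_SIGNS[side]
    flexext = signs["shoulder_flexext"] * np.degrees(np.arctan2(v[:, 0], -v[:, 2]))
    abdadd = signs["shoulder_abdadd"] * np.degrees(np.arctan2(v[:, 1], -v[:, 2]))
    return flexext, abdadd


def angle_between_axes(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Unsigned angle between two unit-vector series, degrees, in [0, 180]."""
    xa = np.atleast_2d(xa)
    xb = np.atleast_2d(xb)
    dot = np.clip(np.sum(xa * xb, axis=-1), -1.0, 1.0)
    cross = np.linalg.norm(np.cross(xa, xb), axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def _signed_flexion(proximal: Rotation, distal: Rotation) -> np.ndarray:
    """Angle between the segments' x-axes, flexion-positive.

    The unsigned angle is signed by the sense of the rotation about the
    proximal segment's mediolateral (y) axis: flexion corresponds to the
    distal x-axis swinging against that axis' right-hand sense.
    """
    xp = np.atleast_2d(_x_axis(proximal))
    xd = np.atleast_2d(_x_axis(distal))
    yp = np.atleast_2d(_y_axis(proximal))
    ang = angle_between_axes(xp, xd)
    s = -np.sign(np.sum(np.cross(xp, xd) * yp, axis=-1))
    s[s == 0] = 1.0
    return s * ang


def elbow_angle(upper_arm: Rotation, lower_arm: Rotation) -> np.ndarray:
    """Elbow flexion: unsigned angle between the arm segments' x-axes."""
    return angle_between_axes(_x_axis(upper_arm), _x_axis(lower_arm))


def forearm_twist(
    upper_arm: Rotation, lower_arm: Rotation, neutral_rel: Rotation, side: str = "left"
) -> np.ndarray:
    """Pronation-supination: twist about the forearm x-axis, supination positive.

    Swing-twist decomposition of the forearm orientation relative to the upper
    arm and the neutral posture; the twist factor about x is read directly off
    the relative quaternion.
    """
    rel = neutral_rel.inv() * (upper_arm.inv() * lower_arm)
    q = np.atleast_2d(rel.as_quat())  # scalar-last (x, y, z, w)
    flip = q[:, 3] < 0
    q[flip] = -q[flip]
    twist = 2.0 * np.arctan2(q[:, 0], q[:, 3])
    return ANGLE_SIGNS[side]["forearm_prosup"] * np.degrees(twist)


def wrist_angle(lower_arm: Rotation, hand: Rotation) -> np.ndarray:
    """Wrist flexion-extension: signed angle between forearm and hand x-axes."""
    return _signed_flexion(lower_arm, hand)


def finger_angle(hand: Rotation, fingertip: Rotation) -> np.ndarray:
    """Finger flexion-extension: signed angle between hand and fingertip x-axes."""
    return _signed_flexion(hand, fingertip)


def capture_neutral(segment_rotations: dict[str, Rotation], window_mask: np.ndarray) -> NeutralReference:
    """Average the neutral-pose window into the per-trial reference."""
    idx = np.where(np.asarray(window_mask, dtype=bool))[0]
    if len(idx) == 0:
        raise ValueError("empty neutral window")
    trunk = segment_rotations["trunk"][idx].mean()
    rel = (segment_rotations["upper_arm"][idx].inv() * segment_rotations["lower_arm"][idx]).mean()
    return NeutralReference(trunk=trunk, forearm_rel_upper=rel)


def joint_angles_from_segments(
    t: np.ndarray,
    seg: dict[str, Rotation],
    side: str = "left",
    neutral: NeutralReference | None = None,
    neutral_window: tuple[float, float] | None = None,
) -> JointAngleSeries:
    """All eleven DOF series from per-segment orientation trajectories.

    `seg` maps segment name -> Rotation of length len(t) (anatomical frame in
    the global frame).  The neutral reference is either given or captured from
    `neutral_window` (time interval of a quiet standing pose in this trial).
    """
    t = np.asarray(t, dtype=float)
    if neutral is None:
        if neutral_window is None:
            raise ValueError("need a neutral reference or a neutral window")
        mask = (t >= neutral_window[0]) & (t < neutral_window[1])
        neutral = capture_neutral(seg, mask)
    tf, tl, tt = trunk_angles(seg["trunk"], neutral.trunk, side)
    sf, sa = shoulder_angles(seg["upper_arm"], seg["trunk"], side)
    angles = {
        "trunk_flexion": tf,
        "trunk_lateral": tl,
        "trunk_torsion": tt,
        "shoulder_flexext": sf,
        "shoulder_abdadd": sa,
        "elbow_flexext": elbow_angle(seg["upper_arm"], seg["lower_arm"]),
        "forearm_prosup": forearm_twist(seg["upper_arm"], seg["lower_arm"], neutral.forearm_rel_upper, side),
        "wrist_flexext": wrist_angle(seg["lower_arm"], seg["hand"]),
        "thumb_flexext": finger_angle(seg["hand"], seg["thumb"]),
        "index_flexext": finger_angle(seg["hand"], seg["index"]),
        "middle_flexext": finger_angle(seg["hand"], seg["middle"]),
    }
    return JointAngleSeries(t=t, angles=angles, side=side, neutral=neutral)
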