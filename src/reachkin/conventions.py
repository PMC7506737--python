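"""Shared conventions: sites, segments, degrees of freedom, sign tables.

Frames
------
Global frame: Z up, Y mediolateral (the hip-flexion rotation axis, pointing to
the subject's left), X = Y x Z anterior.  Gravity is (0, 0, -9.81) m/s^2 and an
accelerometer at rest reads the specific force R^T (0, 0, +9.81) in its own
frame, where R rotates sensor-frame vectors into the global frame.

Segment anatomical frames: for the arm, hand and fingertip segments the
anatomical x-axis points distally along the segment (downward in the neutral
standing pose), y is mediolateral and z completes the right-handed triad.
For the trunk, z points up, y mediolateral and x anterior; in the neutral
standing pose the trunk frame coincides with the global frame.

Joint angles follow the convention that positive values indicate flexion,
abduction or supination; negative values extension, adduction or pronation.

Sides
-----
The protocol is mirrored between arms.  All side dependence is concentrated in
two places: the per-pose axis signs of the segment-calibration protocol
(CALIBRATION_SIGNS) and the angle-sign table used when decomposing relative
orientations into named joint angles (ANGLE_SIGNS).  Both are validated by
round-trip tests against the synthetic generator.
"""

from __future__ import annotations

import numpy as np

GRAVITY = 9.81
G_VEC = np.array([0.0, 0.0, -GRAVITY])

ACCEL_RATE = 100.0  # Hz
GYRO_RATE = 200.0  # Hz
LOWPASS_CUTOFF = 10.0  # Hz
PROCESSING_RATE = 100.0  # Hz, common rate after resampling

STATIC_GYRO_THRESHOLD = np.deg2rad(3.0)  # rad/s; below this a sensor is static
MOVEMENT_THRESHOLD = 0.1  # rad/s on the upper-arm gyro norm

SENSOR_SITES = (
    "sternum",
    "shoulder",
    "upper_arm",
    "lower_arm",
    "hand",
    "thumb",
    "index",
    "middle",
)

SEGMENTS = ("trunk", "upper_arm", "lower_arm", "hand", "thumb", "index", "middle")

# The shoulder sensor sits over the scapula and is calibrated with the trunk
# poses; no joint-angle definition uses it directly.
SITE_SEGMENT = {
    "sternum": "trunk",
    "shoulder": "trunk",
    "upper_arm": "upper_arm",
    "lower_arm": "lower_arm",
    "hand": "hand",
    "thumb": "thumb",
    "index": "index",
    "middle": "middle",
}

FINGERS = ("thumb", "index", "middle")

DOF_NAMES = (
    "trunk_flexion",
    "trunk_lateral",
    "trunk_torsion",
    "shoulder_flexext",
    "shoulder_abdadd",
    "elbow_flexext",
    "forearm_prosup",
    "wrist_flexext",
    "thumb_flexext",
    "index_flexext",
    "middle_flexext",
)

ARMS = ("AF", "NAF")
BLOCKS = ("BL", "BW", "BH")
BLOCK_MASS_KG = {"BL": 0.108, "BW": 0.490, "BH": 1.008}
TARGETS = ("Tab1", "Tab2", "Top3", "Top4")
TARGET_HEIGHT = {"Tab1": "Tab", "Tab2": "Tab", "Top3": "Top", "Top4": "Top"}
REPETITIONS = (1, 2, 3)

SIDES = ("left", "right")


def side_factor(side: str) -> int:
    """+1 for the left arm, -1 for the right (mediolateral mirroring)."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    return 1 if side == "left" else -1


# --------------------------------------------------------------------------
# Segment-calibration protocol (ten poses; eight static, two dynamic).
# Each entry: pose id -> (kind, [(sensor_site, axis_label, sign_left,
# sign_right), ...]).  The axis label names which anatomical axis of the
# sensor's segment is observed (gravity direction for static poses, dominant
# rotation axis for dynamic ones); the signs are applied per tested side.
# Note pose 7 carries a negative sign for BOTH sides: with the upper-arm
# x-axis pointing distally, the hanging arm measures "up" as -x on either arm.
# --------------------------------------------------------------------------
CALIBRATION_PROTOCOL = {
    1: ("static", [("hand", "z", +1, +1), ("index", "z", +1, +1), ("middle", "z", +1, +1)]),
    2: ("static", [("hand", "y", -1, +1), ("index", "y", -1, +1), ("middle", "y", -1, +1)]),
    3: ("static", [("thumb", "z", +1, +1)]),
    4: ("static", [("thumb", "y", +1, -1)]),
    5: ("static", [("lower_arm", "z", +1, +1)]),
    6: ("dynamic", [("lower_arm", "x", +1, -1)]),
    7: ("static", [("upper_arm", "x", -1, -1)]),
    8: ("dynamic", [("upper_arm", "z", +1, +1)]),
    9: ("static", [("sternum", "z", +1, +1), ("shoulder", "z", +1, +1)]),
    10: ("dynamic", [("sternum", "y", +1, -1), ("shoulder", "y", +1, -1)]),
}

STATIC_POSES = tuple(p for p, (k, _) in CALIBRATION_PROTOCOL.items() if k == "static")
DYNAMIC_POSES = tuple(p for p, (k, _) in CALIBRATION_PROTOCOL.items() if k == "dynamic")

# Which two labeled axes build each segment frame, in (primary, secondary)
# order.  The primary axis (the better-observed one) is kept exact; the
# secondary is re-orthogonalised against it; the third follows by cross
# product in right-handed x, y, z label order.
SEGMENT_AXIS_PLAN = {
    "trunk": ("z", "y"),
    "upper_arm": ("x", "z"),
    "lower_arm": ("z", "x"),
    "hand": ("z", "y"),
    "thumb": ("z", "y"),
    "index": ("z", "y"),
    "middle": ("z", "y"),
}

# Signs applied to decomposed joint angles per tested side so that the
# reported angles follow the flexion/abduction/supination-positive convention
# regardless of the mirrored segment frames the calibration protocol yields.
# Validated by generator round-trip and mirror-consistency tests.
ANGLE_SIGNS = {
    "left": {
        "trunk_flexion": +1,
        "trunk_lateral": +1,
        "trunk_torsion": +1,
        "shoulder_flexext": +1,
        "shoulder_abdadd": +1,
        "forearm_prosup": -1,
    },
    "right": {
        "trunk_flexion": -1,
        "trunk_lateral": +1,
        "trunk_torsion": -1,
        "shoulder_flexext": -1,
        "shoulder_abdadd": +1,
        "forearm_prosup": +1,
    },
}
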