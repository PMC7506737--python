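"""Sensor-recording data model, file layout, filtering and bias estimation.

An :class:`ImuStream` keeps the accelerometer (100 Hz) and gyroscope (200 Hz)
channels on their own time bases until :func:`resample_stream` puts both on a
common uniform grid.  A :class:`SensorSet` bundles the eight sensor sites of
the trunk-to-fingertip chain plus up to three fingertip force channels.

On disk a sensor set is a directory with one CSV per site (columns
``t, ax, ay, az, gx, gy, gz``; rows without an accelerometer sample leave the
``a*`` cells empty), one CSV per force channel (``t, f``) and a
``manifest.json`` naming sites, rates and trial condition.  Numeric text is
written with 17 significant digits so a write/read round trip is bit exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .conventions import (
    ACCEL_RATE,
    BLOCK_MASS_KG,
    FINGERS,
    GYRO_RATE,
    SENSOR_SITES,
    STATIC_GYRO_THRESHOLD,
)

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A required stream or field is missing from a recording."""


class CalibrationError(ValueError):
    """A calibration recording does not satisfy the protocol preconditions."""


def _check_times(t: np.ndarray, what: str) -> None:
    if t.ndim != 1:
        raise ValueError(f"{what}: time must be 1-D")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{what}: timestamps must be strictly increasing")
    if not np.all(np.isfinite(t)):
        raise ValueError(f"{what}: non-finite timestamps")


@dataclass
class ImuStream:
    """Triaxial accelerometer + gyroscope record for one sensor site.

    accel is in m/s^2 (specific force, gravity inclusive), gyro in rad/s.
    """

    site: str
    t_accel: np.ndarray
    accel: np.ndarray
    t_gyro: np.ndarray
    gyro: np.ndarray
    accel_rate: float = ACCEL_RATE
    gyro_rate: float = GYRO_RATE

    def __post_init__(self) -> None:
        self.t_accel = np.asarray(self.t_accel, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.t_gyro = np.asarray(self.t_gyro, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.site not in SENSOR_SITES:
            raise SchemaError(f"unknown sensor site {self.site!r}")
        _check_times(self.t_accel, f"{self.site} accel")
        _check_times(self.t_gyro, f"{self.site} gyro")
        for name, arr, t in (("accel", self.accel, self.t_accel), ("gyro", self.gyro, self.t_gyro)):
            if arr.shape != (len(t), 3):
                raise ValueError(f"{self.site} {name}: expected shape ({len(t)}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.site} {name}: non-finite samples")
        for name, t, rate in (("accel", self.t_accel, self.accel_rate), ("gyro", self.t_gyro, self.gyro_rate)):
            if len(t) >= 2:
                span = t[-1] - t[0]
                expected = span * rate + 1
                if abs(len(t) - expected) > max(2.0, 0.01 * expected):
                    raise ValueError(
                        f"{self.site} {name}: {len(t)} samples inconsistent with "
                        f"{rate} Hz over {span:.3f} s"
                    )

    @property
    def aligned(self) -> bool:
        """True when both channels share one uniform time base."""
        return len(self.t_accel) == len(self.t_gyro) and np.array_equal(self.t_accel, self.t_gyro)

    @property
    def t(self) -> np.ndarray:
        if not self.aligned:
            raise ValueError(f"{self.site}: channels not on a common time base; resample first")
        return self.t_gyro

    @property
    def span(self) -> tuple[float, float]:
        return (
            min(self.t_accel[0], self.t_gyro[0]),
            max(self.t_accel[-1], self.t_gyro[-1]),
        )

    def slice(self, t0: float, t1: float) -> "ImuStream":
        """Samples with t in the half-open window [t0, t1)."""
        ma = (self.t_accel >= t0) & (self.t_accel < t1)
        mg = (self.t_gyro >= t0) & (self.t_gyro < t1)
        return replace(
            self,
            t_accel=self.t_accel[ma],
            accel=self.accel[ma],
            t_gyro=self.t_gyro[mg],
            gyro=self.gyro[mg],
        )


@dataclass
class ForceChannel:
    """Fingertip force-sensitive-resistor channel (unitless, baseline near 0)."""

    finger: str
    t: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.finger not in FINGERS:
            raise SchemaError(f"unknown finger {self.finger!r}")
        _check_times(self.t, f"force[{self.finger}]")
        if self.force.shape != self.t.shape:
            raise ValueError(f"force[{self.finger}]: length mismatch")
        if not np.all(np.isfinite(self.force)):
            raise ValueError(f"force[{self.finger}]: non-finite samples")


@dataclass(frozen=True)
class TrialCondition:
    arm: str  # AF | NAF
    block: str  # BL | BW | BH
    target: str  # Tab1 | Tab2 | Top3 | Top4
    repetition: int = 1

    def __post_init__(self) -> None:
        if self.arm not in ("AF", "NAF"):
            raise ValueError(f"arm must be AF or NAF, got {self.arm!r}")
        if self.block not in BLOCK_MASS_KG:
            raise ValueError(f"block must be one of {tuple(BLOCK_MASS_KG)}, got {self.block!r}")
        if self.target not in ("Tab1", "Tab2", "Top3", "Top4"):
            raise ValueError(f"unknown target {self.target!r}")
        if not 1 <= int(self.repetition) <= 3:
            raise ValueError("repetition must be in 1..3")

    @property
    def mass_kg(self) -> float:
        return BLOCK_MASS_KG[self.block]

    @property
    def height(self) -> str:
        return "Top" if self.target.startswith("Top") else "Tab"

    def label(self) -> str:
        return f"{self.arm}_{self.block}_{self.target}_r{self.repetition}"


@dataclass
class SensorSet:
    """All eight IMU streams of one recording plus available force channels."""

    streams: dict[str, ImuStream]
    forces: dict[str, ForceChannel] = field(default_factory=dict)
    condition: TrialCondition | None = None
    side: str | None = None
    #: trials begin with a neutral-pose capture and posture setup; analysis
    #: (movement detection) starts here
    analysis_start: float = 0.0

    def __post_init__(self) -> None:
        missing = [s for s in SENSOR_SITES if s not in self.streams]
        if missing:
            raise SchemaError(f"missing IMU stream(s): {', '.join(missing)}")
        spans = np.array([self.streams[s].span for s in SENSOR_SITES])
        if np.ptp(spans[:, 0]) > 0.1 or np.ptp(spans[:, 1]) > 0.1:
            raise ValueError("sensor streams do not cover a common time span within 0.1 s")

    def map_streams(self, fn) -> "SensorSet":
        return replace(self, streams={k: fn(v) for k, v in self.streams.items()})


@dataclass
class SensorBias:
    site: str
    accel_bias: np.ndarray
    gyro_bias: np.ndarray
    gyro_bias_bound: float = 0.2  # rad/s sanity bound

    def __post_init__(self) -> None:
        self.accel_bias = np.asarray(self.accel_bias, dtype=float).reshape(3)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float).reshape(3)
        if np.linalg.norm(self.gyro_bias) >= self.gyro_bias_bound:
            raise CalibrationError(
                f"{self.site}: gyro bias {self.gyro_bias} exceeds {self.gyro_bias_bound} rad/s"
            )

    def apply(self, stream: ImuStream) -> ImuStream:
        return replace(stream, accel=stream.accel - self.accel_bias, gyro=stream.gyro - self.gyro_bias)


# --------------------------------------------------------------------------
# Filtering / resampling
# --------------------------------------------------------------------------

def lowpass_filter(stream: ImuStream, cutoff: float = 10.0, order: int = 2) -> ImuStream:
    """Zero-phase Butterworth low-pass of both channels.

    A 2nd-order filter run forward and backward (effective 4th order) keeps
    event timing unbiased.  The cutoff must be below the Nyquist rate of every
    channel.
    """
    out = {}
    for name, arr, rate in (("accel", stream.accel, stream.accel_rate), ("gyro", stream.gyro, stream.gyro_rate)):
        if cutoff >= rate / 2:
            raise ValueError(f"cutoff {cutoff} Hz >= Nyquist of {name} channel ({rate / 2} Hz)")
        if len(arr) == 0:
            out[name] = arr
            continue
        b, a = butter(order, cutoff, fs=rate)
        padlen = min(3 * max(len(a), len(b)), len(arr) - 1)
        out[name] = filtfilt(b, a, arr, axis=0, padlen=padlen)
    return replace(stream, accel=out["accel"], gyro=out["gyro"])


def resample_stream(stream: ImuStream, rate: float = 100.0) -> ImuStream:
    """Linearly interpolate both channels onto a uniform grid at `rate`.

    The grid covers the overlap of the two channels' spans so no channel is
    extrapolated.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(stream.t_accel) == 0 or len(stream.t_gyro) == 0:
        raise ValueError(f"{stream.site}: cannot resample an empty stream")
    t0 = max(stream.t_accel[0], stream.t_gyro[0])
    t1 = min(stream.t_accel[-1], stream.t_gyro[-1])
    n = int(np.floor((t1 - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate
    accel = np.column_stack([np.interp(t, stream.t_accel, stream.accel[:, i]) for i in range(3)])
    gyro = np.column_stack([np.interp(t, stream.t_gyro, stream.gyro[:, i]) for i in range(3)])
    return replace(
        stream, t_accel=t, accel=accel, t_gyro=t, gyro=gyro, accel_rate=rate, gyro_rate=rate
    )


def preprocess_stream(
    stream: ImuStream,
    cutoff: float = 10.0,
    rate: float = 100.0,
    bias: SensorBias | None = None,
) -> ImuStream:
    """Standard conditioning: low-pass, resample to the common rate, de-bias."""
    out = resample_stream(lowpass_filter(stream, cutoff), rate)
    if bias is not None:
        out = bias.apply(out)
    return out


# --------------------------------------------------------------------------
# Static (box) bias estimation
# --------------------------------------------------------------------------

def estimate_static_bias(
    box_recording: dict[str, ImuStream],
    static_gyro_sd_threshold: float = 0.05,
) -> SensorBias:
    """Estimate constant sensor biases from the six-orientation box recording.

    The sensor is placed in a rigid box that is set down on each of its six
    faces, so each sensor axis sees +g and -g once.  The gyroscope bias is the
    mean angular rate over all static segments.  For each accelerometer axis,
    the (+g, -g) pair of segment means sums to twice the bias, so the bias is
    half that sum and corrected readings are +/-9.81 m/s^2.
    """
    if len(box_recording) < 6:
        raise CalibrationError(
            f"need at least 6 box orientations, got {len(box_recording)}"
        )
    site = next(iter(box_recording.values())).site
    gyro_means = []
    accel_means = []
    for label, seg in box_recording.items():
        if seg.t_gyro[-1] - seg.t_gyro[0] < 1.0:
            raise CalibrationError(f"box segment {label!r}: shorter than 1 s")
        if np.std(seg.gyro, axis=0).max() > static_gyro_sd_threshold:
            import warnings

            warnings.warn(f"box segment {label!r}: gyro not static", stacklevel=2)
        gyro_means.append(seg.gyro.mean(axis=0))
        accel_means.append(seg.accel.mean(axis=0))
    accel_means = np.array(accel_means)
    accel_bias = np.empty(3)
    for k in range(3):
        hi = accel_means[np.argmax(accel_means[:, k]), k]
        lo = accel_means[np.argmin(accel_means[:, k]), k]
        accel_bias[k] = (hi + lo) / 2.0
    return SensorBias(site=site, accel_bias=accel_bias, gyro_bias=np.mean(gyro_means, axis=0))


def detect_static_mask(gyro: np.ndarray, threshold: float = STATIC_GYRO_THRESHOLD) -> np.ndarray:
    """True where the angular-velocity norm is below the static threshold."""
    return np.linalg.norm(np.asarray(gyro, dtype=float), axis=-1) < threshold


# --------------------------------------------------------------------------
# On-disk layout
# --------------------------------------------------------------------------

def write_imu_csv(path: str | Path, stream: ImuStream) -> Path:
    """One stream as CSV (t, ax..az, gx..gz; NaN cells where no sample)."""
    path = Path(path)
    t = np.union1d(stream.t_accel, stream.t_gyro)
    df = pd.DataFrame({"t": t})
    for cols, tt, arr in (("ax ay az", stream.t_accel, stream.accel), ("gx gy gz", stream.t_gyro, stream.gyro)):
        idx = np.searchsorted(t, tt)
        block = np.full((len(t), 3), np.nan)
        block[idx] = arr
        for j, c in enumerate(cols.split()):
            df[c] = block[:, j]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_imu_csv(
    path: str | Path, site: str, accel_rate: float = ACCEL_RATE, gyro_rate: float = GYRO_RATE
) -> ImuStream:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # noqa: BLE001 - reported with file context
        raise SchemaError(f"{path}: parse error: {e}") from e
    need = {"t", "ax", "ay", "az", "gx", "gy", "gz"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    ma = df[["ax", "ay", "az"]].notna().all(axis=1).to_numpy()
    mg = df[["gx", "gy", "gz"]].notna().all(axis=1).to_numpy()
    return ImuStream(
        site=site,
        t_accel=df["t"].to_numpy()[ma],
        accel=df[["ax", "ay", "az"]].to_numpy()[ma],
        t_gyro=df["t"].to_numpy()[mg],
        gyro=df[["gx", "gy", "gz"]].to_numpy()[mg],
        accel_rate=accel_rate,
        gyro_rate=gyro_rate,
    )


def write_sensor_set(path: str | Path, sset: SensorSet) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sites": {},
        "forces": sorted(sset.forces),
        "side": sset.side,
        "analysis_start": sset.analysis_start,
        "condition": None,
    }
    if sset.condition is not None:
        c = sset.condition
        manifest["condition"] = {
            "arm": c.arm,
            "block": c.block,
            "target": c.target,
            "repetition": c.repetition,
        }
    for site, st in sset.streams.items():
        manifest["sites"][site] = {"accel_rate": st.accel_rate, "gyro_rate": st.gyro_rate}
        write_imu_csv(path / f"imu_{site}.csv", st)
    for finger, fc in sset.forces.items():
        pd.DataFrame({"t": fc.t, "f": fc.force}).to_csv(
            path / f"force_{finger}.csv", index=False, float_format=_FLOAT_FMT
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_sensor_set(path: str | Path) -> SensorSet:
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise SchemaError(f"{path}: no manifest.json")
    try:
        manifest = json.loads(mf.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{mf}: malformed JSON at line {e.lineno}: {e.msg}") from e
    streams = {}
    for site in SENSOR_SITES:
        f = path / f"imu_{site}.csv"
        if not f.exists():
            raise SchemaError(f"{path}: missing required stream {site!r} ({f.name})")
        rates = manifest.get("sites", {}).get(site, {})
        streams[site] = read_imu_csv(
            f,
            site,
            accel_rate=float(rates.get("accel_rate", ACCEL_RATE)),
            gyro_rate=float(rates.get("gyro_rate", GYRO_RATE)),
        )
    forces = {}
    for finger in manifest.get("forces", []):
        df = pd.read_csv(path / f"force_{finger}.csv", float_precision="round_trip")
        forces[finger] = ForceChannel(finger=finger, t=df["t"].to_numpy(), force=df["f"].to_numpy())
    condition = None
    if manifest.get("condition"):
        condition = TrialCondition(**manifest["condition"])
    return SensorSet(
        streams=streams,
        forces=forces,
        condition=condition,
        side=manifest.get("side"),
        analysis_start=float(manifest.get("analysis_start", 0.0)),
    )
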