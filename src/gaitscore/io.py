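"""File formats: IMU trial CSVs, feature tables, model parameters.

On disk, gyroscope values are degrees/second and accelerometer values are
g (the sensor's native ranges are +/-1000 deg/s and +/-8 g); in memory the
package works in SI units (rad/s, m/s^2).  Readers validate and reject,
they never clip, reorder or resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ModelError
from .model import ScorerParams, validate_params

G_MPS2 = 9.80665  #: standard gravity, m/s^2

GYRO_RANGE_DPS = 1000.0  #: sensor gyroscope range, deg/s
ACCEL_RANGE_G = 8.0  #: sensor accelerometer range, g

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]

#: Canonical feature column order (Table of gait parameters).
FEATURE_NAMES = [
    "SL", "GD", "PSP", "MH", "RL", "RSZ",
    "RSY", "RSX", "MPV", "MVV", "MSV", "MHD",
]

#: Features normalised by subject height.
HEIGHT_NORMALIZED = ["SL", "MH", "RL", "MPV", "MVV", "MHD"]


@dataclass
class TrialMeta:
    """Per-trial metadata: subject identity, body height, clinical rating."""

    subject_id: str
    height: float
    rated_level: int | None = None
    group: str = "pd"  # healthy | pd

    def __post_init__(self):
        if not 0.5 < self.height < 2.5:
            raise DataError(f"implausible height {self.height} m (expected 0.5-2.5)")
        if self.rated_level is not None and self.rated_level not in (0, 1, 2, 3, 4):
            raise DataError(f"rated_level must be in 0..4, got {self.rated_level}")
        if self.group not in ("healthy", "pd"):
            raise DataError(f"group must be 'healthy' or 'pd', got {self.group!r}")


@dataclass
class ImuSeries:
    """One shank's 6-axis IMU stream in SI units.

    ``time`` is seconds, strictly increasing, nominally 100 Hz.  Sensor
    axes: X inferior-superior (static specific force reads -1 g on X when
    the shank is vertical), Y anterior-posterior, Z mediolateral.
    """

    time: np.ndarray
    gyro: np.ndarray  #: (n, 3) rad/s
    accel: np.ndarray  #: (n, 3) m/s^2
    side: str = "right"
    rate_hz: float = 100.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)

    def __len__(self):
        return self.time.shape[0]

    @property
    def gyro_dps(self):
        """Angular velocity in deg/s (file units)."""
        return np.degrees(self.gyro)

    @property
    def dt(self):
        """Median sampling interval, s."""
        return float(np.median(np.diff(self.time)))


def validate_imu_series(series: ImuSeries, rate_hz: float | None = None) -> ImuSeries:
    """Check the stream invariants; raise :class:`DataError` on violation."""
    n = len(series)
    if series.gyro.shape != (n, 3) or series.accel.shape != (n, 3):
        raise FormatError("gyro/accel must be (n, 3) arrays matching time")
    if n >= 2 and not np.all(np.diff(series.time) > 0):
        raise DataError("time column is not strictly increasing")
    nominal = rate_hz or series.rate_hz
    if n >= 2:
        dt = series.dt
        if abs(dt - 1.0 / nominal) > 0.01 / nominal:
            raise DataError(
                f"median sampling interval {dt:.5f} s deviates >1% from "
                f"nominal {1.0 / nominal:.5f} s"
            )
    gyro_dps = np.abs(series.gyro_dps)
    accel_g = np.abs(series.accel) / G_MPS2
    bad = (gyro_dps > GYRO_RANGE_DPS).any(axis=1) | (accel_g > ACCEL_RANGE_G).any(axis=1)
    if bad.mean() > 0.01:
        raise DataError(
            f"{bad.sum()} of {n} samples exceed the sensor range "
            f"(+/-{GYRO_RANGE_DPS:g} deg/s, +/-{ACCEL_RANGE_G:g} g)"
        )
    if series.side not in ("left", "right"):
        raise DataError(f"side must be 'left' or 'right', got {series.side!r}")
    return series


def read_imu_csv(path, side: str = "right", rate_hz: float = 100.0) -> ImuSeries:
    """Read one shank's trial CSV (columns t,gx,gy,gz,ax,ay,az; s, deg/s, g).

    Rows violating the sensor-range invariant cause rejection of the whole
    file (beyond a 1% tolerance for isolated glitches); values are never
    clipped.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df[IMU_COLUMNS].isna().any().any():
        raise DataError(f"{path}: missing values in required columns")
    series = ImuSeries(
        time=df["t"].to_numpy(float),
        gyro=np.radians(df[["gx", "gy", "gz"]].to_numpy(float)),
        accel=df[["ax", "ay", "az"]].to_numpy(float) * G_MPS2,
        side=side,
        rate_hz=rate_hz,
    )
    return validate_imu_series(series, rate_hz)


def write_imu_csv(path, series: ImuSeries) -> None:
    """Write an :class:`ImuSeries` back to the trial CSV layout (file units)."""
    df = pd.DataFrame(
        np.column_stack([series.time, series.gyro_dps, series.accel / G_MPS2]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a per-subject feature table CSV (index subject_id).

    Columns: the twelve canonical feature names plus ``rated_level`` and
    ``group``.
    """
    df = pd.read_csv(path, index_col="subject_id")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing feature column(s) {missing}")
    if df[FEATURE_NAMES].isna().any().any():
        raise DataError(f"{path}: missing cells in feature columns")
    return df


def write_feature_table(path, table: pd.DataFrame) -> None:
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=True, index_label="subject_id")


def write_model_json(path, params: ScorerParams) -> None:
    """Serialise scorer parameters to JSON at full precision."""
    validate_params(params)
    payload = {
        "w": list(params.w),
        "c": params.c,
        "p": list(params.p),
        "bl": params.bl,
        "bu": params.bu,
        "features": list(params.features),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model_json(path) -> ScorerParams:
    """Read scorer parameters; raises :class:`ModelError` if infeasible."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    try:
        params = ScorerParams(
            w=np.asarray(payload["w"], dtype=float),
            c=float(payload["c"]),
            p=np.asarray(payload["p"], dtype=float),
            features=list(payload.get("features", [])),
            bl=float(payload.get("bl", -0.5)),
            bu=float(payload.get("bu", 4.5)),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc
    return validate_params(params)
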