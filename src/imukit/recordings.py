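"""Containers and plain-text I/O for raw IMU recordings.

A recording is one sensor worn during one task of one session: tri-axial
accelerometer (m/s^2) and gyroscope (rad/s) sampled at 128 Hz.  Files are
CSV with header ``t,ax,ay,az,gx,gy,gz`` (t in seconds); a cohort manifest
is CSV with one row per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidSizeError

MANIFEST_COLUMNS = [
    "subject_id",
    "session_id",
    "diagnosis",
    "severity",
    "bars_total",
    "bars_right_arm",
    "bars_arm_leg",
    "task",
    "side",
    "sensor",
    "path",
]


@dataclass
class RecordingMeta:
    subject_id: str
    session_id: str
    task: str  # fnf | ahm | hs
    side: str  # left | right
    sensor: str  # wrist | ankle


@dataclass
class IMURecording:
    """One sensor x session x task tri-axial accel + gyro time series."""

    fs_hz: float
    accel: np.ndarray  # (T, 3), m/s^2
    gyro: np.ndarray  # (T, 3), rad/s
    meta: RecordingMeta = field(
        default_factory=lambda: RecordingMeta("?", "?", "fnf", "right", "wrist")
    )

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise InvalidSizeError(
                f"accel {self.accel.shape} and gyro {self.gyro.shape} must both be (T, 3)"
            )

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


def write_recording(rec: IMURecording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        np.column_stack([rec.times_s, rec.accel, rec.gyro]),
        columns=["t", "ax", "ay", "az", "gx", "gy", "gz"],
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording(path: str | Path, meta: RecordingMeta | None = None) -> IMURecording:
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 128.0
    rec = IMURecording(
        fs_hz=float(round(fs, 6)),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
    )
    if meta is not None:
        rec.meta = meta
    return rec


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"subject_id": str, "session_id": str}, keep_default_na=True
    )
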