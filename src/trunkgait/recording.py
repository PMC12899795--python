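"""In-memory container and delimited-file I/O for 6-channel trunk IMU signals.

A recording holds tri-axial acceleration in g, ordered (VT, ML, AP) =
(vertical, mediolateral, anteroposterior), and tri-axial angular velocity
in deg/s, ordered (yaw, pitch, roll) = rotations about the (VT, ML, AP)
axes. The on-disk format is a UTF-8 CSV with header columns::

    time_s, acc_vt_g, acc_ml_g, acc_ap_g, gyr_yaw_dps, gyr_pitch_dps, gyr_roll_dps
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NonUniformRateError, SchemaError

ACC_AXES = ("vt", "ml", "ap")
GYR_AXES = ("yaw", "pitch", "roll")

ACC_COLUMNS = tuple(f"acc_{a}_g" for a in ACC_AXES)
GYR_COLUMNS = tuple(f"gyr_{a}_dps" for a in GYR_AXES)
TIME_COLUMN = "time_s"


@dataclass
class ImuRecording:
    """Uniform-rate 6-channel lower-trunk IMU signal.

    Attributes
    ----------
    acc : (n, 3) float array, g, columns ordered (VT, ML, AP).
    gyr : (n, 3) float array, deg/s, columns ordered (yaw, pitch, roll).
    sample_rate_hz : sampling rate, > 0.
    """

    acc: np.ndarray
    gyr: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must be an (n, 3) array (VT, ML, AP)")
        if self.gyr.ndim != 2 or self.gyr.shape[1] != 3:
            raise ValueError("gyr must be an (n, 3) array (yaw, pitch, roll)")
        if self.acc.shape[0] != self.gyr.shape[0]:
            raise ValueError("acc and gyr must have equal length")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyr).all()):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def slice(self, start: int, stop: int) -> "ImuRecording":
        """Return the half-open sample span [start, stop) as a new recording."""
        if not (0 <= start < stop <= self.n_samples):
            raise ValueError(f"span [{start}, {stop}) outside recording bounds")
        return ImuRecording(
            acc=self.acc[start:stop].copy(),
            gyr=self.gyr[start:stop].copy(),
            sample_rate_hz=self.sample_rate_hz,
        )

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by axis name ('vt','ml','ap','yaw','pitch','roll')."""
        if name in ACC_AXES:
            return self.acc[:, ACC_AXES.index(name)]
        if name in GYR_AXES:
            return self.gyr[:, GYR_AXES.index(name)]
        raise KeyError(name)


def write_recording(recording: ImuRecording, path) -> None:
    """Write a recording to CSV at full float precision (round-trip safe)."""
    df = pd.DataFrame({TIME_COLUMN: recording.time_s})
    for i, col in enumerate(ACC_COLUMNS):
        df[col] = recording.acc[:, i]
    for i, col in enumerate(GYR_COLUMNS):
        df[col] = recording.gyr[:, i]
    df.to_csv(path, index=False, float_format="%.17g")


def read_recording(path, jitter_tol: float = 0.10) -> ImuRecording:
    """Read a recording CSV, validating schema and timestamp uniformity.

    Parameters
    ----------
    jitter_tol : maximum tolerated timestamp deviation, as a fraction of the
        nominal sample period (default 10%).

    Raises
    ------
    SchemaError : a required channel column is absent (named in the message).
    NonUniformRateError : timestamp jitter exceeds ``jitter_tol``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = (TIME_COLUMN,) + ACC_COLUMNS + GYR_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing channel column(s): {', '.join(missing)}")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) < 2:
        raise NonUniformRateError("need at least 2 samples to establish a rate")
    dt = np.diff(t)
    period = float(np.median(dt))
    if period <= 0:
        raise NonUniformRateError("timestamps are not strictly increasing")
    if np.abs(dt - period).max() > jitter_tol * period:
        raise NonUniformRateError(
            f"timestamp jitter exceeds {jitter_tol:.0%} of the nominal period "
            f"({period:.6g} s)"
        )
    acc = df[list(ACC_COLUMNS)].to_numpy(dtype=float)
    gyr = df[list(GYR_COLUMNS)].to_numpy(dtype=float)
    return ImuRecording(acc=acc, gyr=gyr, sample_rate_hz=1.0 / period)
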