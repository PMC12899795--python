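"""Alignment, steady-segment isolation and length normalization.

Tilt correction follows the walking-average inclination idea of
Moe-Nilssen: the mean acceleration vector over a steady segment estimates
the gravity direction in the sensor frame, and two successive elementary
rotations (pitch about ML, then roll about AP) bring it onto the vertical
axis, so corrected AP and ML channels average zero and VT averages the
measured gravity magnitude. Angular-velocity channels are rotated by the
same proper rotation.

Turns are excluded on a smoothed absolute yaw-rate threshold; the
surviving straight-walking spans are truncated to a common stride count
(default 18) and resampled once, globally, to strides × 200 samples so
that one stride maps to ~200 points for the nonlinear analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .errors import GravityReferenceError, InsufficientDataError
from .events import GaitEvents, dominant_step_period
from .recording import ImuRecording


@dataclass
class WalkSegment:
    """Half-open sample span [start, stop) of steady walking in a recording."""

    source: ImuRecording
    start: int
    stop: int
    condition: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.stop <= self.source.n_samples):
            raise ValueError(
                f"span [{self.start}, {self.stop}) outside recording bounds"
            )

    @property
    def n_samples(self) -> int:
        return self.stop - self.start

    @property
    def acc(self) -> np.ndarray:
        return self.source.acc[self.start : self.stop]

    @property
    def gyr(self) -> np.ndarray:
        return self.source.gyr[self.start : self.stop]

    @property
    def sample_rate_hz(self) -> float:
        return self.source.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.source.channel(name)[self.start : self.stop]


@dataclass
class NormalizedSignal:
    """1-D signal resampled to exactly n_strides × samples_per_stride points."""

    values: np.ndarray
    n_strides: int
    samples_per_stride: int = 200

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_strides * self.samples_per_stride:
            raise ValueError(
                f"length {len(self.values)} != "
                f"{self.n_strides} strides x {self.samples_per_stride}"
            )

    def __len__(self) -> int:
        return len(self.values)


def _gravity_rotation(mean_acc: np.ndarray) -> np.ndarray:
    """Proper rotation mapping the mean acceleration onto (+|g|, 0, 0).

    Built from two elementary rotations: pitch about ML zeroes the AP mean,
    then roll about AP zeroes the ML mean.
    """
    vt, ml, ap = mean_acc
    theta_p = np.arctan2(ap, vt)
    # after undoing pitch: vt' = cos*vt + sin*ap, ml unchanged, ap' = 0
    cp, sp = np.cos(theta_p), np.sin(theta_p)
    r_pitch = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    v1 = r_pitch @ mean_acc
    theta_r = np.arctan2(v1[1], v1[0])
    cr, sr = np.cos(theta_r), np.sin(theta_r)
    r_roll = np.array([[cr, sr, 0.0], [-sr, cr, 0.0], [0.0, 0.0, 1.0]])
    return r_roll @ r_pitch


def tilt_correct(recording: ImuRecording) -> ImuRecording:
    """Rotate sensor axes so mean acceleration is purely vertical.

    Requires the mean acceleration magnitude to be a plausible gravity
    reference (0.5–1.5 g); rejects free-fall-like or clipped input. The
    operation is idempotent and norm-preserving per sample.
    """
    if recording.duration_s < 2.0:
        raise InsufficientDataError(
            "need at least 2 s of signal to estimate mean orientation"
        )
    mean_acc = recording.acc.mean(axis=0)
    mag = float(np.linalg.norm(mean_acc))
    if not (0.5 <= mag <= 1.5):
        raise GravityReferenceError(
            f"mean acceleration magnitude {mag:.3f} g is not a usable "
            "gravity reference (expected 0.5-1.5 g)"
        )
    rot = _gravity_rotation(mean_acc)
    assert np.isclose(np.linalg.det(rot), 1.0, atol=1e-9)
    return ImuRecording(
        acc=recording.acc @ rot.T,
        gyr=recording.gyr @ rot.T,
        sample_rate_hz=recording.sample_rate_hz,
    )


def exclude_turns(
    recording: ImuRecording,
    yaw_thresh_dps: float = 50.0,
    min_dur_s: float = 0.5,
    smooth_window_s: float = 0.5,
    stride_period_s: float | None = None,
    condition: str | None = None,
) -> list[WalkSegment]:
    """Split a recording into maximal straight-walking segments.

    A sample is 'turning' when the moving-average absolute yaw rate meets
    ``yaw_thresh_dps``; turning runs shorter than ``min_dur_s`` are treated
    as spikes and kept as walking. Straight spans shorter than 3 stride
    periods are dropped. Returns an empty list when nothing qualifies.
    """
    if yaw_thresh_dps <= 0 or min_dur_s <= 0:
        raise ValueError("thresholds must be positive")
    fs = recording.sample_rate_hz
    yaw = recording.gyr[:, 0]
    w = max(1, int(round(smooth_window_s * fs)))
    smoothed = uniform_filter1d(np.abs(yaw), size=w, mode="nearest")
    turning = smoothed >= yaw_thresh_dps

    # suppress sub-min_dur_s turning spikes, then pad surviving turn runs by
    # the smoothing half-width so the lagged threshold crossing cannot leak
    # turn samples into the straight segments
    min_run = int(round(min_dur_s * fs))
    turning = _drop_short_runs(turning, min_run)
    turning = _dilate_runs(turning, w // 2 + 1)

    if stride_period_s is None:
        step = dominant_step_period(recording.acc[:, 2], fs)
        stride_period_s = 2.0 * step / fs if step is not None else 2.0
    min_len = int(round(3 * stride_period_s * fs))

    segments: list[WalkSegment] = []
    for start, stop in _runs(~turning):
        if stop - start >= min_len:
            segments.append(WalkSegment(recording, start, stop, condition))
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _dilate_runs(mask: np.ndarray, pad: int) -> np.ndarray:
    out = mask.copy()
    n = len(mask)
    for start, stop in _runs(mask):
        out[max(0, start - pad) : min(n, stop + pad)] = True
    return out


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    out = mask.copy()
    for start, stop in _runs(mask):
        if stop - start < min_run:
            out[start:stop] = False
    return out


def truncate_to_strides(
    segment: WalkSegment, events: GaitEvents, n_strides: int = 18
) -> WalkSegment:
    """Truncate a segment to its first ``n_strides`` strides.

    The span runs from the first step instant to the step instant
    2·n_strides later; when the segment holds exactly 2·n_strides steps
    (no trailing step instant) the span extends to the segment end.
    Event indices are interpreted relative to the segment start.
    """
    available = events.n_strides
    if available < n_strides:
        raise InsufficientDataError(
            f"{available} strides available, {n_strides} requested"
        )
    idx = events.step_indices
    first = int(idx[0])
    if len(idx) > 2 * n_strides:
        last = int(idx[2 * n_strides])
    else:
        last = segment.n_samples
    return WalkSegment(
        source=segment.source,
        start=segment.start + first,
        stop=segment.start + last,
        condition=segment.condition,
    )


def resample_to_normalized(
    values: np.ndarray,
    n_strides: int,
    samples_per_stride: int = 200,
) -> NormalizedSignal:
    """Resample a truncated signal once, globally, to n_strides × 200 points.

    Piecewise-cubic interpolation on a uniform target grid; the time
    mapping is monotone (a single linear re-gridding, not per-stride
    warping) and the endpoints are preserved exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("input signal is empty")
    if n_strides < 3:
        raise InsufficientDataError("need at least 3 strides to normalize")
    target = n_strides * samples_per_stride
    if target < 2:
        raise ValueError("target length must be at least 2")
    if x.size == target:
        return NormalizedSignal(x.copy(), n_strides, samples_per_stride)
    if x.size < 4:
        raise InsufficientDataError("need at least 4 samples for cubic resampling")
    grid = np.linspace(0.0, x.size - 1.0, target)
    out = CubicSpline(np.arange(x.size), x)(grid)
    out[0], out[-1] = x[0], x[-1]
    return NormalizedSignal(out, n_strides, samples_per_stride)
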