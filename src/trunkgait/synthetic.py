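"""Synthetic trunk-IMU walking signals with known gait-quality ground truth.

The generator emulates steady-state walking as seen by a lower-back (L5/S1)
IMU: vertical (VT) and anteroposterior (AP) acceleration oscillate once per
step (twice per stride), while mediolateral (ML) acceleration and yaw
angular velocity alternate sign with each step, i.e. repeat at stride
periodicity. Left/right asymmetry is imposed as a per-step amplitude
scaling — left steps scaled by (1 + asymmetry_ratio), right steps by
(1 − asymmetry_ratio) — which weakens step-lag self-similarity while
leaving stride-lag similarity intact, exactly the contrast the symmetry
metrics measure. Static sensor tilt rotates the gravity vector into the
ML/AP channels; turning segments superimpose a sustained, ramped yaw rate.

The waveform family is a sum of sinusoids at step/stride harmonics whose
per-step envelope changes only at waveform zero crossings, so the signal is
continuous and, for asymmetry_ratio = 0 and noise_sd = 0, exactly
stride-periodic. All randomness flows from ``rng_seed``: identical config
and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, SensorRangeError
from .recording import ImuRecording

ACC_RANGE_G = 8.0
GYR_RANGE_DPS = 1000.0


def _rot_about_ml(theta: float) -> np.ndarray:
    """Pitch rotation (about the ML axis) in (VT, ML, AP) coordinates."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _rot_about_ap(theta: float) -> np.ndarray:
    """Roll rotation (about the AP axis) in (VT, ML, AP) coordinates."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class SimulationConfig:
    """Parameters of one simulated walking trial.

    Amplitudes are in g (acceleration) and deg/s (angular velocity);
    ``asymmetry_ratio`` in [0, 1) scales left/right steps by (1 ± ratio);
    ``tilt_deg`` is (pitch, roll) static sensor misalignment;
    ``turn_segments`` is a list of (start_s, duration_s, yaw_rate_deg_s).
    """

    duration_s: float = 30.0
    sample_rate_hz: float = 200.0
    stride_freq_hz: float = 1.0
    step_amp_vt: float = 0.25
    step_amp_ap: float = 0.20
    ml_amp: float = 0.12
    asymmetry_ratio: float = 0.0
    noise_sd: float = 0.0
    gyro_noise_sd: float = 0.0
    tilt_deg: tuple[float, float] = (0.0, 0.0)
    turn_segments: list[tuple[float, float, float]] = field(default_factory=list)
    rng_seed: int = 0
    # gyro oscillation amplitudes (yaw alternates sign per step, i.e. stride
    # periodicity; pitch/roll carry smaller step-frequency content)
    yaw_amp_dps: float = 25.0
    pitch_amp_dps: float = 8.0
    roll_amp_dps: float = 12.0

    def validate(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not (0.0 <= self.asymmetry_ratio < 1.0):
            raise ValueError("asymmetry_ratio must be in [0, 1)")
        if self.noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.duration_s * self.stride_freq_hz < 3:
            raise InsufficientDataError(
                "config represents fewer than 3 strides "
                f"({self.duration_s * self.stride_freq_hz:.2f})"
            )


@dataclass
class GroundTruth:
    """Constructed events of a simulated trial.

    step_times_s are the exact AP-acceleration peak instants; laterality
    strictly alternates starting with 'L'; turn_mask flags every sample that
    lies inside a commanded turn segment (ramps included).
    """

    step_times_s: np.ndarray
    laterality: list[str]
    stride_period_s: float
    turn_mask: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.step_times_s)

    @property
    def n_strides(self) -> int:
        return self.n_steps // 2

    def step_indices(self, sample_rate_hz: float) -> np.ndarray:
        return np.round(self.step_times_s * sample_rate_hz).astype(int)


def _turn_profile(t: np.ndarray, segments, ramp_s: float = 0.25):
    """Superimposed yaw rate from turn segments: plateau with cosine ramps."""
    yaw = np.zeros_like(t)
    mask = np.zeros(t.shape, dtype=bool)
    for start, dur, rate in segments:
        seg = (t >= start) & (t < start + dur)
        mask |= seg
        local = t[seg] - start
        shape = np.ones(local.shape)
        r = min(ramp_s, dur / 2)
        if r > 0:
            up = local < r
            shape[up] = 0.5 * (1 - np.cos(np.pi * local[up] / r))
            down = local > dur - r
            shape[down] = 0.5 * (1 - np.cos(np.pi * (dur - local[down]) / r))
        yaw[seg] += rate * shape
    return yaw, mask


def simulate_walk(config: SimulationConfig) -> tuple[ImuRecording, GroundTruth]:
    """Generate one walking trial and its ground-truth event structure.

    Returns a sensor-frame recording (gravity included, tilt applied,
    noise added) plus the exact step times, laterality and turn mask used
    to build it.
    """
    config.validate()
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    f_stride = config.stride_freq_hz
    f_step = 2.0 * f_stride
    t_step = 1.0 / f_step

    # per-step amplitude envelope: left (even) steps 1+a, right (odd) 1-a
    step_index = np.floor(t / t_step).astype(int)
    a = config.asymmetry_ratio
    env = np.where(step_index % 2 == 0, 1.0 + a, 1.0 - a)

    step_wave = np.sin(2 * np.pi * f_step * t)        # zero at step boundaries
    step_wave2 = np.sin(4 * np.pi * f_step * t)       # 2nd harmonic, also zero
    stride_wave = np.sin(2 * np.pi * f_stride * t)    # sign alternates per step

    # AP is a pure fundamental so ground-truth peak times are exact
    ap = config.step_amp_ap * env * step_wave
    vt = 1.0 + config.step_amp_vt * env * (step_wave + 0.3 * step_wave2)
    ml = config.ml_amp * env * stride_wave

    yaw_turn, turn_mask = _turn_profile(t, config.turn_segments)
    yaw = config.yaw_amp_dps * env * stride_wave + yaw_turn
    pitch = config.pitch_amp_dps * env * step_wave2
    roll = config.roll_amp_dps * env * stride_wave

    acc = np.column_stack([vt, ml, ap])
    gyr = np.column_stack([yaw, pitch, roll])

    # static sensor misalignment: roll about AP composed with pitch about ML
    p_rad, r_rad = np.deg2rad(config.tilt_deg)
    rot = _rot_about_ap(r_rad) @ _rot_about_ml(p_rad)
    acc = acc @ rot.T
    gyr = gyr @ rot.T

    rng = np.random.default_rng(config.rng_seed)
    if config.noise_sd > 0:
        acc = acc + config.noise_sd * rng.standard_normal(acc.shape)
    if config.gyro_noise_sd > 0:
        gyr = gyr + config.gyro_noise_sd * rng.standard_normal(gyr.shape)

    if np.abs(acc).max() > ACC_RANGE_G:
        raise SensorRangeError(
            f"acceleration exceeds ±{ACC_RANGE_G:g} g sensor range"
        )
    if np.abs(gyr).max() > GYR_RANGE_DPS:
        raise SensorRangeError(
            f"angular velocity exceeds ±{GYR_RANGE_DPS:g} deg/s sensor range"
        )

    # AP peaks sit at phase 1/4 within each step interval
    n_steps = int(math.floor(config.duration_s / t_step - 0.25)) + 1
    step_times = (np.arange(n_steps) + 0.25) * t_step
    step_times = step_times[step_times < config.duration_s]
    laterality = ["L" if k % 2 == 0 else "R" for k in range(len(step_times))]

    truth = GroundTruth(
        step_times_s=step_times,
        laterality=laterality,
        stride_period_s=1.0 / f_stride,
        turn_mask=turn_mask,
    )
    recording = ImuRecording(acc=acc, gyr=gyr, sample_rate_hz=fs)
    return recording, truth
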