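"""Step and stride symmetry from trunk-acceleration autocorrelation.

The signal's similarity with its one-step- and one-stride-delayed copies
is read off the unbiased autocorrelation: the dominant extremum near the
step lag gives step symmetry, the dominant peak near the stride lag gives
stride symmetry; coefficients closer to 1 mean a more repeatable gait.
For the ML axis the trunk sways in opposite directions on left and right
steps, so its step-lag extremum is negative by construction; the reported
ML step value is its absolute value, while VT and AP report the signed
(positive) peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateSignalError, PeakSearchError
from .events import GaitEvents
from .preprocess import NormalizedSignal


@dataclass
class SymmetryResult:
    axis: str
    step_coeff: float            # signed dominant extremum at the step lag
    stride_coeff: float          # dominant peak at the stride lag
    step_lag_samples: int
    stride_lag_samples: int

    @property
    def step_coeff_reported(self) -> float:
        """Reported convention: ML uses the absolute value, VT/AP the signed."""
        return abs(self.step_coeff) if self.axis == "ml" else self.step_coeff


def autocorr_unbiased(
    x: np.ndarray, max_lag: int, biased: bool = False
) -> np.ndarray:
    """Mean-removed autocorrelation, scaled so the lag-0 coefficient is 1.

    Unbiased normalization divides the lag-l product sum by N−l (the
    biased variant, dividing by N, is selectable). Rejects constant input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not (0 < max_lag < n):
        raise ValueError(f"require 0 < max_lag < {n}")
    x = x - x.mean()
    if not np.any(x):
        raise DegenerateSignalError("constant signal has no autocorrelation")
    lags = np.arange(max_lag + 1)
    c = np.array([x[: n - l] @ x[l:] for l in lags])
    if not biased:
        c = c / (n - lags)
    return c / c[0]


def _window(lag: float, frac: float, n: int) -> tuple[int, int]:
    lo = max(1, int(np.floor(lag * (1 - frac))))
    hi = min(n, int(np.ceil(lag * (1 + frac))))
    return lo, hi


def step_stride_symmetry(
    x: NormalizedSignal | np.ndarray,
    axis: str,
    events: GaitEvents | None = None,
    step_lag: float | None = None,
    stride_lag: float | None = None,
    window_frac: float = 0.25,
    biased: bool = False,
) -> SymmetryResult:
    """Step and stride symmetry coefficients for one acceleration axis.

    Lags are anchored to the measured cadence: for a NormalizedSignal one
    stride is samples_per_stride points; otherwise the median step/stride
    periods come from ``events`` (or explicit lags). The dominant
    extremum is searched within ±``window_frac`` of each anchor lag —
    positive peaks for VT/AP and stride symmetry, either sign for the ML
    step lag.
    """
    if axis not in ("vt", "ml", "ap"):
        raise ValueError("axis must be one of 'vt', 'ml', 'ap'")
    if isinstance(x, NormalizedSignal):
        values = x.values
        stride_lag = float(x.samples_per_stride)
        step_lag = stride_lag / 2.0
    else:
        values = np.asarray(x, dtype=float)
        if step_lag is None or stride_lag is None:
            if events is None or events.n_steps < 6:
                raise ValueError(
                    "need events with >= 6 steps (or explicit lags) "
                    "to anchor the search windows"
                )
            step_lag = events.mean_step_period_samples
            stride_lag = events.mean_stride_period_samples

    max_lag = min(len(values) - 1, int(np.ceil(stride_lag * (1 + window_frac))) + 2)
    c = autocorr_unbiased(values, max_lag, biased=biased)

    pos_peaks, _ = find_peaks(c)
    neg_peaks, _ = find_peaks(-c)

    def dominant(lo: int, hi: int, two_sided: bool) -> int:
        cand = pos_peaks[(pos_peaks >= lo) & (pos_peaks <= hi)]
        if two_sided:
            neg = neg_peaks[(neg_peaks >= lo) & (neg_peaks <= hi)]
            cand = np.concatenate([cand, neg])
        if len(cand) == 0:
            raise PeakSearchError(
                f"no autocorrelation extremum in lag window [{lo}, {hi}] "
                f"({axis} axis)"
            )
        return int(cand[np.argmax(np.abs(c[cand]))])

    s_lo, s_hi = _window(step_lag, window_frac, max_lag)
    step_idx = dominant(s_lo, s_hi, two_sided=(axis == "ml"))
    t_lo, t_hi = _window(stride_lag, window_frac, max_lag)
    stride_idx = dominant(t_lo, t_hi, two_sided=False)

    return SymmetryResult(
        axis=axis,
        step_coeff=float(c[step_idx]),
        stride_coeff=float(c[stride_idx]),
        step_lag_samples=step_idx,
        stride_lag_samples=stride_idx,
    )
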