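"""SPARC spectral arc-length smoothness of angular-velocity channels.

SPARC (Balasubramanian et al.) measures movement smoothness as the
negated arc length of the amplitude-normalized magnitude spectrum over an
adaptively truncated low-frequency band: the spectrum is computed with
generous zero padding, normalized to its maximum, cut at ``cutoff_hz``
(10 Hz), then further truncated at the highest frequency whose normalized
magnitude still reaches ``amp_threshold`` (0.05); the frequency axis is
rescaled by that adaptive band so the metric is dimensionless. Values are
always negative; smaller absolute values (arc closer to the ideal smooth
spectrum) mean smoother movement. Because the metric depends on absolute
frequency content, it is computed on the native-rate signal, not on the
stride-normalized resampled series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError


@dataclass
class SparcParams:
    # zero_pad_factor 128 resolves the spectral-window sidelobe structure of
    # quasi-periodic signals; at coarser padding the polyline arc length is
    # not resolution-converged (see docs/methods.md)
    cutoff_hz: float = 10.0
    amp_threshold: float = 0.05
    zero_pad_factor: int = 128

    def validate(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if not (0 < self.amp_threshold < 1):
            raise ValueError("amp_threshold must be in (0, 1)")
        if self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be >= 1")


@dataclass
class SmoothnessResult:
    axis: str
    sparc: float                 # negative; |smaller| = smoother
    adaptive_cutoff_hz: float    # <= cutoff_hz


def normalized_spectrum(
    omega: np.ndarray, sample_rate_hz: float, p: SparcParams
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded magnitude spectrum up to cutoff, normalized to its max."""
    x = np.asarray(omega, dtype=float)
    nfft = int(2 ** np.ceil(np.log2(len(x) * p.zero_pad_factor)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate_hz)
    mag = np.abs(np.fft.rfft(x, nfft))
    sel = freqs <= p.cutoff_hz
    f_sel, m_sel = freqs[sel], mag[sel]
    peak = m_sel.max()
    if peak == 0:
        raise DegenerateSignalError("signal has no spectral content below cutoff")
    return f_sel, m_sel / peak


def sparc(
    omega: np.ndarray,
    sample_rate_hz: float,
    p: SparcParams | None = None,
    axis: str = "",
) -> SmoothnessResult:
    """SPARC of one angular-velocity channel.

    Requires ≥ 2 s of non-constant signal. The arc length is the summed
    Euclidean increments of the normalized spectrum curve with the
    frequency axis scaled by the adaptive band width.
    """
    p = p or SparcParams()
    p.validate()
    x = np.asarray(omega, dtype=float)
    if len(x) < 2 * sample_rate_hz:
        raise ValueError("need at least 2 s of signal for SPARC")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("zero-variance signal has undefined SPARC")

    f_sel, m_norm = normalized_spectrum(x, sample_rate_hz, p)
    above = np.flatnonzero(m_norm >= p.amp_threshold)
    band = slice(above[0], above[-1] + 1)
    f_band, m_band = f_sel[band], m_norm[band]
    if len(f_band) < 2:
        raise DegenerateSignalError("adaptive band contains fewer than 2 bins")
    f_span = f_band[-1] - f_band[0]
    arc = float(
        np.sum(np.sqrt((np.diff(f_band) / f_span) ** 2 + np.diff(m_band) ** 2))
    )
    return SmoothnessResult(
        axis=axis, sparc=-arc, adaptive_cutoff_hz=float(f_band[-1])
    )
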