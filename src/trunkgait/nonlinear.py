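"""Nonlinear gait-quality measures: local dynamic stability, regularity
and complexity.

Stability is the maximum finite-time Lyapunov exponent computed with the
Rosenstein nearest-neighbour scheme extended to multiple (k = 7)
neighbours per reference point: after delay embedding (m = 5, τ = 10),
each reference's neighbours — excluding temporally adjacent points within
±0.5 stride — are followed over a 10-stride horizon, and λ_max is the
least-squares slope of the mean log Euclidean separation over the early
part of the divergence curve, expressed per stride (the length
normalization fixes one stride ≈ 200 samples). λ_max near zero means
parallel, non-diverging trajectories (a stable, repeatable gait); larger
values mean faster divergence and lower stability.

Regularity is sample entropy (SaEn), the negative log conditional
probability that runs matching for m points also match for m + 1
(Chebyshev distance, tolerance r × SD, self-matches excluded). Complexity
is multiscale entropy (MSE): SaEn of coarse-grained (non-overlapping
window-averaged) copies of the series across scales 1..6, with the
tolerance fixed from the original series' SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist, pdist

from .errors import DegenerateSignalError, InsufficientDataError
from .preprocess import NormalizedSignal


@dataclass
class EmbeddingParams:
    """State-space reconstruction and divergence-tracking parameters."""

    dim_m: int = 5
    delay_tau: int = 10
    n_neighbors_k: int = 7
    exclusion_strides: float = 0.5      # Theiler-style temporal exclusion
    window_strides: float = 10.0        # divergence tracking horizon
    fit_span_strides: tuple[float, float] = (0.0, 0.5)

    def validate(self) -> None:
        if self.dim_m < 2 and self.dim_m != 1:
            raise ValueError("dim_m must be >= 2 (or 1 for identity embedding)")
        if self.delay_tau < 1 or self.n_neighbors_k < 1:
            raise ValueError("delay_tau and n_neighbors_k must be >= 1")


@dataclass
class EntropyParams:
    """Sample-entropy / multiscale-entropy parameters."""

    template_m: int = 2
    tolerance_r: float = 0.2            # fraction of the series SD
    n_scales: int = 6

    def validate(self) -> None:
        if self.template_m < 1:
            raise ValueError("template_m must be >= 1")
        if self.tolerance_r <= 0:
            raise ValueError("tolerance_r must be positive")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


@dataclass
class StabilityResult:
    lambda_max: float                   # per-stride divergence rate
    divergence_curve: np.ndarray        # mean ln distance vs sample offset
    fit_span: tuple[int, int]           # sample-offset interval used for slope
    n_reference_points: int


@dataclass
class EntropyResult:
    saen: float
    mse_by_scale: np.ndarray            # one SaEn per scale 1..n_scales
    mse_summary: float                  # mean over finite scales
    flagged: bool = False               # True when any scale was infinite


def embed(x, dim_m: int, delay_tau: int) -> np.ndarray:
    """Delay embedding: row i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ})."""
    values = x.values if isinstance(x, NormalizedSignal) else np.asarray(x, float)
    n = len(values)
    span = (dim_m - 1) * delay_tau
    if n <= span:
        raise InsufficientDataError(
            f"need more than {span} samples for m={dim_m}, tau={delay_tau} "
            f"(got {n})"
        )
    cols = [values[j * delay_tau : n - span + j * delay_tau] for j in range(dim_m)]
    return np.column_stack(cols)


def max_lyapunov(
    x: NormalizedSignal | np.ndarray,
    p: EmbeddingParams | None = None,
    samples_per_stride: int | None = None,
) -> StabilityResult:
    """Rosenstein maximum Lyapunov exponent with k nearest neighbours.

    ``samples_per_stride`` sets the time base (λ is reported per stride);
    it is inferred from a NormalizedSignal and must be given for raw
    arrays (use 1 to express λ per sample/iteration).
    """
    p = p or EmbeddingParams()
    p.validate()
    if isinstance(x, NormalizedSignal):
        if samples_per_stride is None:
            samples_per_stride = x.samples_per_stride
        if x.n_strides <= p.window_strides:
            raise InsufficientDataError(
                f"need more than {p.window_strides:g} strides to track a "
                f"{p.window_strides:g}-stride divergence window"
            )
        values = x.values
    else:
        if samples_per_stride is None:
            raise ValueError("samples_per_stride required for raw arrays")
        values = np.asarray(x, dtype=float)

    sps = samples_per_stride
    traj = embed(values, p.dim_m, p.delay_tau)
    window = int(round(p.window_strides * sps))
    theiler = int(np.ceil(p.exclusion_strides * sps))
    n_traj = len(traj)
    n_ref = n_traj - window
    k = p.n_neighbors_k
    if n_ref < k + 2:
        raise InsufficientDataError(
            "too few trackable reference points for the requested window"
        )

    # pairwise distances among trackable points; temporal exclusion as +inf
    dist = cdist(traj[:n_ref], traj[:n_ref])
    for i in range(n_ref):
        lo = max(0, i - theiler)
        dist[i, lo : i + theiler + 1] = np.inf

    admissible = np.isfinite(dist).sum(axis=1)
    ok = admissible >= k
    if (~ok).sum() > 0.1 * n_ref:
        raise InsufficientDataError(
            f"fewer than k={k} admissible neighbours for "
            f"{(~ok).sum()}/{n_ref} reference points"
        )
    refs = np.flatnonzero(ok)
    order = np.argpartition(dist[refs], kth=k - 1, axis=1)[:, :k]

    i_idx = np.repeat(refs, k)
    j_idx = order.ravel()
    # distances at the double-precision roundoff floor carry no divergence
    # information (e.g. an exactly periodic signal); clamp them so the log
    # curve stays flat instead of tracking accumulated rounding error
    scale = float(np.sqrt(np.mean(traj**2)))
    floor = max(1e-12 * scale, np.finfo(float).tiny)
    curve = np.empty(window + 1)
    for t in range(window + 1):
        d = np.linalg.norm(traj[i_idx + t] - traj[j_idx + t], axis=1)
        curve[t] = np.mean(np.log(np.maximum(d, floor)))

    lo = int(round(p.fit_span_strides[0] * sps))
    hi = int(round(p.fit_span_strides[1] * sps))
    hi = min(max(hi, lo + 1), window)
    t_strides = np.arange(lo, hi + 1) / sps
    slope = np.polyfit(t_strides, curve[lo : hi + 1], 1)[0]

    return StabilityResult(
        lambda_max=float(slope),
        divergence_curve=curve,
        fit_span=(lo, hi),
        n_reference_points=len(refs),
    )


def _template_match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered-pair match counts for templates of length m and m+1.

    Both counts use the N−m template start positions (Richman–Moorman
    convention); a match requires every elementwise distance < r
    (Chebyshev norm); self-matches excluded.
    """
    n = len(x)
    if n < m + 2:
        raise InsufficientDataError(f"series too short for m={m}")
    tm = sliding_window_view(x, m)[: n - m]
    tm1 = sliding_window_view(x, m + 1)
    b = int((pdist(tm, "chebyshev") < r).sum())
    a = int((pdist(tm1, "chebyshev") < r).sum())
    return a, b


def sample_entropy(
    x: NormalizedSignal | np.ndarray,
    p: EntropyParams | None = None,
    r_abs: float | None = None,
) -> float:
    """Sample entropy −ln(A/B); returns +inf when no (m+1)-matches exist.

    ``r_abs`` overrides the tolerance with an absolute value (used by the
    multiscale computation, which fixes r from the original series).
    """
    p = p or EntropyParams()
    p.validate()
    values = x.values if isinstance(x, NormalizedSignal) else np.asarray(x, float)
    if len(values) < 100:
        raise InsufficientDataError("need at least 100 samples for SaEn")
    sd = float(values.std())
    if sd == 0:
        raise DegenerateSignalError("zero-variance signal has undefined SaEn")
    r = r_abs if r_abs is not None else p.tolerance_r * sd
    a, b = _template_match_counts(values, p.template_m, r)
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means; scale 1 returns the input unchanged."""
    values = x.values if isinstance(x, NormalizedSignal) else np.asarray(x, float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale == 1:
        return values
    n_out = len(values) // scale
    if n_out < 1 or len(values) < 2 * scale:
        raise InsufficientDataError(f"series too short for scale {scale}")
    return values[: n_out * scale].reshape(n_out, scale).mean(axis=1)


def multiscale_entropy(
    x: NormalizedSignal | np.ndarray,
    p: EntropyParams | None = None,
) -> EntropyResult:
    """SaEn across coarse-graining scales 1..n_scales (fixed tolerance).

    The tolerance is r × SD of the ORIGINAL series at every scale (Costa
    convention). The summary is the mean over finite scales; infinite
    scales are excluded with a warning and the result flagged.
    """
    p = p or EntropyParams()
    p.validate()
    values = x.values if isinstance(x, NormalizedSignal) else np.asarray(x, float)
    if len(values) < 100 * p.n_scales:
        raise InsufficientDataError(
            f"need >= {100 * p.n_scales} samples so the coarsest of "
            f"{p.n_scales} scales keeps >= 100 points"
        )
    sd = float(values.std())
    if sd == 0:
        raise DegenerateSignalError("zero-variance signal has undefined MSE")
    r = p.tolerance_r * sd
    by_scale = np.empty(p.n_scales)
    for s in range(1, p.n_scales + 1):
        by_scale[s - 1] = sample_entropy(coarse_grain(values, s), p, r_abs=r)
    finite = np.isfinite(by_scale)
    flagged = not finite.all()
    if flagged:
        warnings.warn(
            f"{(~finite).sum()} of {p.n_scales} MSE scales had no template "
            "matches; excluded from the summary"
        )
    summary = float(by_scale[finite].mean()) if finite.any() else float("inf")
    return EntropyResult(
        saen=float(by_scale[0]),
        mse_by_scale=by_scale,
        mse_summary=summary,
        flagged=flagged,
    )
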