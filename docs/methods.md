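# Methods

`trunkgait` computes gait-quality parameters from a single lower-trunk
(L5/S1) IMU recording 6 channels at a nominal 200 Hz: tri-axial
acceleration in g along the vertical (VT), mediolateral (ML) and
anteroposterior (AP) body axes, and tri-axial angular velocity in deg/s
about the same axes (yaw, pitch, roll). This note documents the models,
the parameter choices that matter, the synthetic-data generator's scope,
and the numerical decisions.

## Processing chain

1. **Tilt correction** (`preprocess.tilt_correct`). The mean acceleration
   vector over the analysed segment estimates the gravity direction in
   the sensor frame (walking-average inclination in the spirit of
   Moe-Nilssen's trunk-accelerometry correction). Two successive
   elementary rotations — pitch about ML to zero the mean AP, then roll
   about AP to zero the mean ML — form a proper rotation (det = +1)
   applied to both acceleration and angular velocity. After correction
   the mean acceleration is (|g|, 0, 0). The operation is idempotent and
   preserves per-sample vector norms. Inputs whose mean acceleration
   magnitude falls outside 0.5–1.5 g (free fall, clipping) are rejected:
   there is no usable gravity reference. A walking average is used rather
   than a separate static-standing calibration window because recordings
   are assumed to contain walking only; a standing window can be passed
   explicitly by slicing the recording first.

2. **Turn exclusion** (`preprocess.exclude_turns`). Turning is flagged
   where a 0.5 s moving-average |yaw rate| meets a threshold (default
   50 deg/s); above-threshold runs shorter than 0.5 s are treated as
   spikes, surviving runs are padded by the smoothing half-width so the
   lagged threshold crossing cannot leak turn samples into straight
   segments. Straight spans shorter than 3 stride periods are dropped.
   Both thresholds are config-exposed; no reference values exist for this
   sensor, so the defaults were chosen to separate sustained turning
   (~100 deg/s plateaus) from the ±25 deg/s yaw oscillation of straight
   walking with a wide margin.

3. **Step events** (`events`). Steps are the characteristic AP
   acceleration peaks (one per step; a stride is two consecutive steps).
   The detector is self-tuning: the dominant step period comes from the
   AP autocorrelation (with a half-lag check so that an asymmetry-raised
   stride peak does not masquerade as the step period), the signal is
   zero-phase low-pass filtered at 3× the step frequency (wide
   sinusoid-like peaks otherwise split into several noise-made local
   maxima), and peaks must clear a prominence of 0.3× the interquartile
   range with a minimum separation of 0.4× the step period. Inter-step
   gaps longer than 1.75× the median interval (midway between one and two
   step periods) trigger one local peak search per gap, automating the
   manual repair of near-merged peak pairs under strong asymmetry;
   inserted steps are flagged. Laterality is the sign of the mean yaw
   rate over each step-to-step interval; the sign→side mapping is
   trial-relative (mounting-dependent), which is harmless because all
   downstream metrics are side-agnostic. Sub-noise-floor intervals are
   labelled by alternation and flagged.

4. **Truncation and length normalization** (`preprocess`). All trials are
   truncated to a common stride count (default 18 — roughly the least
   number of strides a short clinical walkway yields after turn
   exclusion; config-exposed) spanning the first
   step instant to the step instant 2·n later, then each channel is
   resampled **once, globally** to n_strides × 200 samples with a cubic
   spline on a uniform grid (monotone time mapping, endpoints preserved;
   exactly reproduces affine signals). This fixes the time base one
   stride ≈ 200 samples ≈ 1 s used by the nonlinear analyses; it is not
   per-stride time warping, so within-trial stride-duration variability
   is preserved.

## Gait-quality parameters

**Step/stride symmetry** — unbiased autocorrelation (mean-removed, lag-l
sum divided by N−l, lag-0 scaled to 1; biased variant selectable). The
step coefficient is the dominant extremum within ±25% of the step lag,
the stride coefficient the dominant peak within ±25% of the stride lag;
anchoring the search windows to the measured cadence avoids harmonic
confusion. On the normalized signal these lags are 100 and 200 samples.
ML trunk sway alternates sign with each step, so its step-lag extremum is
negative by construction; the extremum is searched with either sign and
summary tables report its absolute value (VT/AP report the signed peak).
Coefficients closer to 1 mean a more repeatable gait.

**Stability** — maximum finite-time Lyapunov exponent, Rosenstein scheme
with a multi-neighbour extension: delay embedding with m = 5, τ = 10; for
each reference point the k = 7 nearest Euclidean neighbours outside a
±0.5-stride temporal exclusion window are followed over a 10-stride
horizon; λ_max is the least-squares slope of the mean log separation over
the first 0.5 stride (short-term slope convention; span config-exposed,
full divergence curve retained), expressed per stride. Distances at the
double-precision roundoff floor (below 10⁻¹² of the trajectory RMS) are
clamped: an exactly periodic signal has neighbour separations of order
machine epsilon whose drift reflects accumulated rounding, not dynamics,
and clamping yields the correct λ ≈ 0 there. Reference points must leave
room for the full horizon; if more than 10% of reference points lack k
admissible neighbours the input is rejected.

**Regularity** — sample entropy, Richman–Moorman convention: templates of
length m = 2 from the N−m start positions, Chebyshev distance, match when
every elementwise distance < r = 0.2 × SD, self-matches excluded;
SaEn = −ln(A/B) with A the (m+1)-matches; +∞ when A = 0. A smooth
periodic signal has small but nonzero SaEn (~0.1–0.2): templates at
mirrored phases around the extrema match at length m but not m+1. "Near
zero" is therefore relative to the ~1–2 typical of noisy gait.

**Complexity** — multiscale entropy: SaEn of non-overlapping
window-averaged copies at scales 1..6, tolerance fixed at 0.2 × SD of the
*original* series (Costa convention; per-scale re-normalization
selectable). Scale 1 shares the SaEn code path, so the identity
mse[1] = SaEn is exact. The single complexity summary is the mean over
finite scales (the reduction is not standardized in the field; the mean
is the default here and all per-scale values are reported); infinite
scales are excluded with a warning and the result flagged.

**Smoothness** — SPARC (Balasubramanian et al.): magnitude spectrum of
the native-rate angular-velocity channel with generous zero padding,
normalized to its maximum below the 10 Hz cutoff; the band is truncated
at the highest frequency whose normalized magnitude still reaches 0.05;
SPARC is the negated polyline arc length of the normalized curve with the
frequency axis scaled by the band width. It is computed on the truncated
steady-walking span at native rate — not the stride-normalized series —
because the metric depends on absolute frequency content (a resampled
mode is available by passing the normalized values and effective rate).
Default `zero_pad_factor` is 128: the rectangular-window sidelobe wiggle
of quasi-periodic signals converges only first-order in frequency
resolution, and at the conventional 4× padding the arc length is ~5–10%
short of its converged value (and changes by several percent per pad
doubling). At 128× a further doubling moves SPARC by < 0.5% and the
value agrees with a spline/trapezoid-refined integration of the curve to
< 0.1%. Values are always negative; smaller |SPARC| = smoother. Note
that by construction SPARC is insensitive to broadband noise whose
normalized spectral level stays below the 0.05 amplitude threshold —
the monotone noise-degradation property applies to content that is
spectrally visible above it.

**Display inversion** — spider-plot-style displays negate SaEn and λ_max
(so "closer to the edge" uniformly means better) and show ML step
symmetry as an absolute value; all tabular outputs keep the original,
untransformed values.

## Statistics

Per-outcome group comparisons are OLS of `outcome ~ group + gender
(+ walking_speed)` with the control group as reference, so negative
estimates mean lower values in the patient (OA) group. Designs with a
single-level factor or other collinearity are rejected naming the term.
Habitual→fast adaptation is tested with a linear mixed model (fixed:
Group, Condition, Group × Condition, gender, optionally speed; random:
participant intercept). Estimates come from the REML fit; the interaction
p-value from a 1-df likelihood-ratio test of ML refits — a
language-agnostic choice that avoids denominator-degrees-of-freedom
conventions. p-value families (one per comparison table: per condition ×
adjustment, and the interaction set) are adjusted with Benjamini–Hochberg
step-up FDR; the family partition is config-level since no single
partition is canonical. Test–retest reliability is ICC(3,1) — two-way
mixed, consistency, single measure: (MS_B − MS_E)/(MS_B + MS_E) for two
sessions; fixed session offsets do not lower it; zero between-subject
variance is rejected as undefined.

## Synthetic gait generator

The generator provides ground truth, not realism. Steady walking is a sum
of sinusoids: VT and AP oscillate once per step (VT adds a 0.3-relative
second harmonic and the +1 g gravity component; AP is a pure fundamental
so ground-truth peak times are exact closed forms), ML acceleration and
yaw angular velocity alternate sign per step (stride periodicity), with
smaller pitch/roll gyro content. Left/right asymmetry scales left steps
by (1+a) and right by (1−a) through a per-step envelope that switches at
waveform zero crossings, so the signal stays continuous and — with a = 0
and no noise — is exactly stride-periodic. Static tilt rotates all
channels by pitch-then-roll elementary rotations; turns superimpose a
constant yaw rate with 0.25 s cosine ramps; noise is i.i.d. Gaussian per
channel. Amplitude defaults (0.25/0.12/0.20 g VT/ML/AP, 25 deg/s yaw)
sit in the range reported for lower-trunk sensors during comfortable
walking; stride rates 0.85–1.15 Hz cover slow-to-brisk adult gait.
Everything derives from one integer seed: identical config + seed is
bit-identical.

What it does **not** model: pathology-specific waveform shapes,
stride-to-stride timing variability (asymmetry is amplitude-only by
default), soft-tissue artifacts, heavier-tailed sensor noise,
magnetometer channels. Consequently, passing tests demonstrate that the
estimators recover known constructed properties (periodicity, asymmetry
level, noise level, turn placement) and match their analytic/brute-force
oracles — not that clinical effect sizes would be reproduced on patient
data.

## Problem sizes and degenerate inputs

Validation workloads are sized for a single CPU: Monte-Carlo checks use
20 seeds per condition (100 for the step-detector hit rate), the
null-FDR calibration 500 outcome-level replicates of 19 outcomes, the
logistic-map Lyapunov check a 3000-point orbit, and full-pipeline cohorts
6–8 participants per arm with symmetry-only metrics. Degenerate inputs
are rejected, never silently coerced: zero-variance series (entropy,
SPARC, autocorrelation), free-fall-like gravity references, fewer strides
than requested (the available count is reported), rank-deficient designs
(the collinear term is named), non-converged mixed models. A pipeline
stage failure aborts the trial with the stage name; partial profiles are
never emitted.

## Known limitations

- The simulator's harmonic waveforms make step detection easier than on
  clinical signals; detector parameters (prominence 0.3 × IQR, separation
  0.4 × step period, repair threshold 1.75× median) are config-exposed
  for harder data.
- λ_max magnitudes depend on the embedding/time-base conventions; values
  are comparable within this pipeline's convention (per stride, m = 5,
  τ = 10), not across packages with other conventions.
- The MSE summary (mean over scales) is one of several reasonable
  reductions; per-scale values are always reported alongside.
- SPARC on short windows retains window-leakage sidelobes inside the
  adaptive band; the high default padding makes the arc length
  resolution-stable but does not remove the leakage itself.
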