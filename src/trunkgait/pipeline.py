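"""End-to-end orchestration: raw trunk-IMU recording → gait-quality profile,
and simulated cohorts → group-comparison reports.

A trial runs tilt correction → turn exclusion → step detection (with gap
repair) → laterality labelling → truncation to a fixed stride count →
global resampling, then computes the six gait-quality parameters: step and
stride symmetry, stability (λ_max), regularity (SaEn) and complexity (MSE)
per acceleration axis, and SPARC smoothness per angular-velocity axis
(native rate). Any stage failure aborts the run with the stage name;
partial profiles are never emitted silently.

Tables always carry the untransformed metric values. For display
(spider-plot style, "closer to the edge = better"), ``invert_for_display``
negates SaEn and λ_max so that higher means more regular/more stable, and
shows ML step symmetry as an absolute value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats as stats_mod
from .errors import GaitError, InsufficientDataError, StageError
from .events import GaitEvents, events_from_detection
from .nonlinear import EmbeddingParams, EntropyParams, max_lyapunov, multiscale_entropy
from .preprocess import (
    NormalizedSignal,
    exclude_turns,
    resample_to_normalized,
    tilt_correct,
    truncate_to_strides,
)
from .recording import ACC_AXES, GYR_AXES, ImuRecording
from .smoothness import SparcParams, sparc
from .symmetry import step_stride_symmetry
from .synthetic import SimulationConfig, simulate_walk

logger = logging.getLogger("trunkgait")

ALL_METRICS = frozenset(
    {"symmetry", "stability", "regularity", "complexity", "smoothness"}
)


@dataclass
class TrialConfig:
    """Every parameter a trial run actually uses (logged for auditability)."""

    n_strides: int = 18
    samples_per_stride: int = 200
    turn_yaw_thresh_dps: float = 50.0
    turn_min_dur_s: float = 0.5
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    sparc: SparcParams = field(default_factory=SparcParams)
    metrics: frozenset[str] = ALL_METRICS

    def log(self) -> None:
        logger.info("trial parameters: %s", dataclasses.asdict(self))


@dataclass
class GaitQualityProfile:
    """The six gait-quality parameters for one trial.

    Acceleration-axis dicts are keyed 'vt'/'ml'/'ap'; rotation-axis dicts
    'yaw'/'pitch'/'roll'. ``step_symmetry`` holds the signed coefficients;
    table/display conventions are applied downstream.
    """

    step_symmetry: dict[str, float] = field(default_factory=dict)
    stride_symmetry: dict[str, float] = field(default_factory=dict)
    lyapunov: dict[str, float] = field(default_factory=dict)
    saen: dict[str, float] = field(default_factory=dict)
    mse_summary: dict[str, float] = field(default_factory=dict)
    sparc: dict[str, float] = field(default_factory=dict)
    mse_by_scale: dict[str, np.ndarray] = field(default_factory=dict)

    def to_series(self, table_convention: bool = True) -> pd.Series:
        """Flatten to named outcomes (e.g. ``step_symmetry_vt``).

        ``table_convention`` reports ML step symmetry as an absolute value
        (the summary-table convention); all other values are untransformed.
        """
        out: dict[str, float] = {}
        for metric, per_axis in (
            ("step_symmetry", self.step_symmetry),
            ("stride_symmetry", self.stride_symmetry),
            ("lyapunov", self.lyapunov),
            ("saen", self.saen),
            ("mse_summary", self.mse_summary),
            ("sparc", self.sparc),
        ):
            for axis, v in per_axis.items():
                if table_convention and metric == "step_symmetry" and axis == "ml":
                    v = abs(v)
                out[f"{metric}_{axis}"] = v
        return pd.Series(out)


def invert_for_display(profile: GaitQualityProfile) -> GaitQualityProfile:
    """Display copy: negate SaEn and λ_max (higher = more regular/stable)
    and show ML step symmetry as an absolute value. Tables keep originals."""
    return replace(
        profile,
        step_symmetry={
            a: (abs(v) if a == "ml" else v)
            for a, v in profile.step_symmetry.items()
        },
        lyapunov={a: -v for a, v in profile.lyapunov.items()},
        saen={a: -v for a, v in profile.saen.items()},
    )


def run_trial(
    recording: ImuRecording,
    config: TrialConfig | None = None,
    return_intermediates: bool = False,
):
    """Process one recording into a GaitQualityProfile.

    Raises StageError naming the failing stage on any error; with
    ``return_intermediates`` also returns a dict of per-stage outputs.
    """
    config = config or TrialConfig()
    config.log()
    inter: dict[str, object] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except GaitError as exc:
            raise StageError(name, exc) from exc
        inter[name] = out
        return out

    corrected = stage("tilt_correct", tilt_correct, recording)
    segments = stage(
        "exclude_turns",
        exclude_turns,
        corrected,
        yaw_thresh_dps=config.turn_yaw_thresh_dps,
        min_dur_s=config.turn_min_dur_s,
    )
    if not segments:
        raise StageError("exclude_turns", "no steady-walking segment found")
    segment = max(segments, key=lambda s: s.n_samples)
    inter["segment"] = segment

    events = stage(
        "detect_steps",
        events_from_detection,
        segment.channel("ap"),
        segment.channel("yaw"),
        segment.sample_rate_hz,
    )
    if events.n_steps < 6:
        raise StageError(
            "detect_steps", f"only {events.n_steps} steps detected; unusable"
        )

    truncated = stage(
        "truncate_to_strides", truncate_to_strides, segment, events, config.n_strides
    )
    events_in_span = events.shifted(truncated.start - segment.start)
    inter["events_in_span"] = events_in_span

    normalized: dict[str, NormalizedSignal] = {}
    for axis in ACC_AXES:
        normalized[axis] = resample_to_normalized(
            truncated.channel(axis), config.n_strides, config.samples_per_stride
        )
    inter["normalized"] = normalized

    profile = GaitQualityProfile()
    try:
        for axis in ACC_AXES:
            if "symmetry" in config.metrics:
                sym = step_stride_symmetry(normalized[axis], axis)
                profile.step_symmetry[axis] = sym.step_coeff
                profile.stride_symmetry[axis] = sym.stride_coeff
            if "stability" in config.metrics:
                profile.lyapunov[axis] = max_lyapunov(
                    normalized[axis], config.embedding
                ).lambda_max
            if "regularity" in config.metrics or "complexity" in config.metrics:
                ent = multiscale_entropy(normalized[axis], config.entropy)
                if "regularity" in config.metrics:
                    profile.saen[axis] = ent.saen
                if "complexity" in config.metrics:
                    profile.mse_summary[axis] = ent.mse_summary
                    profile.mse_by_scale[axis] = ent.mse_by_scale
        if "smoothness" in config.metrics:
            for axis in GYR_AXES:
                profile.sparc[axis] = sparc(
                    truncated.channel(axis), truncated.sample_rate_hz,
                    config.sparc, axis=axis,
                ).sparc
    except GaitError as exc:
        raise StageError("metrics", exc) from exc

    if return_intermediates:
        return profile, inter
    return profile


# ---------------------------------------------------------------------------
# simulated cohorts

#: per-arm simulator settings: the patient (OA) arm walks with marked
#: left/right asymmetry and noisier trunk control than controls.
DEFAULT_GROUP_SIM = {
    "OA": {"asymmetry_ratio": 0.3, "noise_sd": 0.08, "gyro_noise_sd": 4.0,
           "stride_freq_hz": 0.85},
    "control": {"asymmetry_ratio": 0.0, "noise_sd": 0.03, "gyro_noise_sd": 1.5,
                "stride_freq_hz": 0.95},
}

#: walking-speed metadata (mean, SD in m/s) per group × condition
DEFAULT_SPEEDS = {
    ("OA", "habitual"): (0.64, 0.08),
    ("OA", "fast"): (1.62, 0.25),
    ("control", "habitual"): (1.38, 0.15),
    ("control", "fast"): (1.80, 0.17),
}

#: stride-rate increase from habitual to fast walking (Hz)
FAST_STRIDE_BOOST = 0.2


@dataclass
class CohortConfig:
    n_per_group: int = 20
    conditions: tuple[str, ...] = ("habitual", "fast")
    duration_s: float = 30.0
    seed: int = 0
    group_sim: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIM))
    speeds: dict = field(default_factory=lambda: dict(DEFAULT_SPEEDS))
    trial: TrialConfig = field(default_factory=TrialConfig)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate per-participant trials and run the full pipeline on each.

    Returns a tidy frame: one row per participant × condition with
    metadata (participant_id, group, gender, condition, walking_speed)
    plus one column per gait outcome.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    for group, sim_kwargs in config.group_sim.items():
        for _ in range(config.n_per_group):
            pid += 1
            gender = "F" if rng.random() < 0.5 else "M"
            stride_base = sim_kwargs.get("stride_freq_hz", 0.9) + rng.normal(0, 0.04)
            for condition in config.conditions:
                stride = stride_base + (
                    FAST_STRIDE_BOOST if condition == "fast" else 0.0
                )
                sim = SimulationConfig(
                    duration_s=config.duration_s,
                    stride_freq_hz=stride,
                    rng_seed=int(rng.integers(2**31 - 1)),
                    **{k: v for k, v in sim_kwargs.items()
                       if k != "stride_freq_hz"},
                )
                recording, _ = simulate_walk(sim)
                profile = run_trial(recording, config.trial)
                mu, sd = config.speeds.get((group, condition), (1.2, 0.15))
                row = {
                    "participant_id": f"P{pid:03d}",
                    "group": group,
                    "gender": gender,
                    "condition": condition,
                    "walking_speed": float(max(0.2, rng.normal(mu, sd))),
                }
                row.update(profile.to_series().to_dict())
                rows.append(row)
    return pd.DataFrame(rows)


def outcome_columns(records: pd.DataFrame) -> list[str]:
    meta = {"participant_id", "group", "gender", "condition", "walking_speed"}
    return [c for c in records.columns if c not in meta]


def analyze_cohort(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group-comparison report from a tidy trial table.

    Produces per-condition comparisons (unadjusted and speed-adjusted
    BH families) and, when both conditions are present for enough
    participants, the Group × Condition interaction tables.
    """
    outcomes = outcome_columns(records)
    conditions = sorted(records["condition"].astype(str).unique())
    blocks = []
    for condition in conditions:
        sub = records[records["condition"] == condition]
        for adjust in (False, True):
            tab = stats_mod.compare_outcomes(sub, outcomes, adjust_speed=adjust)
            tab.insert(0, "condition", condition)
            tab.insert(1, "speed_adjusted", adjust)
            blocks.append(tab)
    report = {"profiles": records, "comparisons": pd.concat(blocks, ignore_index=True)}

    if len(conditions) >= 2:
        try:
            inter_blocks = []
            for adjust in (False, True):
                tab = stats_mod.interaction_table(
                    records, outcomes, adjust_speed=adjust
                )
                tab.insert(0, "speed_adjusted", adjust)
                inter_blocks.append(tab)
            report["interactions"] = pd.concat(inter_blocks, ignore_index=True)
        except ValueError as exc:
            logger.warning("interaction analysis skipped: %s", exc)
    else:
        logger.warning(
            "interaction analysis skipped: only condition(s) %s present",
            conditions,
        )
    return report


def run_study(config: CohortConfig) -> dict[str, pd.DataFrame]:
    """Simulate a cohort and produce the full comparison report."""
    if config.n_per_group < 2:
        raise InsufficientDataError("need at least 2 participants per group")
    records = simulate_cohort(config)
    return analyze_cohort(records)
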