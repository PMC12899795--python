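"""Group regressions, mixed-model interaction, BH adjustment and ICC —
each held against an independent oracle or a known construction."""

import numpy as np
import pandas as pd
import pytest

from trunkgait import (
    RankDeficiencyError,
    bh_adjust,
    compare_outcomes,
    fit_group_model,
    fit_interaction_model,
    icc_3_1,
)
from trunkgait.errors import DegenerateSignalError


def bh_oracle(p):
    """Textbook step-up BH: sort ascending, adj_i = min_{j>=i} p_j * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def make_records(n_per_group, effect=0.0, noise_sd=0.01, seed=0,
                 speed_coef=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("OA", "control"):
        for i in range(n_per_group):
            speed = rng.normal(1.2 if g == "control" else 0.8, 0.1)
            y = (
                1.0
                + effect * (g == "OA")
                + speed_coef * speed
                + rng.normal(0, noise_sd)
            )
            rows.append(
                dict(
                    participant_id=f"{g}{i}",
                    group=g,
                    gender="F" if i % 2 else "M",
                    condition="habitual",
                    walking_speed=speed,
                    y=y,
                )
            )
    return pd.DataFrame(rows)


class TestGroupModel:
    def test_null_groups_estimate_near_zero(self):
        df = make_records(40, effect=0.0, noise_sd=1.0, seed=1)
        res = fit_group_model(df, "y")
        assert abs(res.estimate) < 3 * res.se
        assert res.p_raw > 0.01

    def test_recovers_built_in_effect(self):
        df = make_records(40, effect=0.5, noise_sd=0.01, seed=2)
        res = fit_group_model(df, "y")
        assert res.estimate == pytest.approx(0.5, abs=0.02)
        assert res.adjusted_for == ["gender"]

    def test_speed_adjustment_absorbs_confound(self):
        # outcome driven entirely by speed; groups differ only via speed
        df = make_records(40, effect=0.0, noise_sd=0.005, seed=3, speed_coef=1.0)
        unadj = fit_group_model(df, "y", adjust_speed=False)
        adj = fit_group_model(df, "y", adjust_speed=True)
        assert abs(unadj.estimate) > 0.2   # confounded
        assert abs(adj.estimate) < 0.02    # absorbed by the covariate
        assert "walking_speed" in adj.adjusted_for

    def test_single_gender_rank_deficiency_named(self):
        df = make_records(10, seed=4)
        df["gender"] = "F"
        with pytest.raises(RankDeficiencyError, match="gender"):
            fit_group_model(df, "y")

    def test_too_few_per_group_rejected(self):
        df = make_records(2, seed=5)
        with pytest.raises(ValueError):
            fit_group_model(df, "y")

    def test_ols_parameter_recovery_bias(self):
        # bias < 2% of the true effect at n=80, noise 10% of effect
        effects = []
        for seed in range(500):
            df = make_records(40, effect=0.5, noise_sd=0.05, seed=seed)
            effects.append(fit_group_model(df, "y").estimate)
        assert abs(np.mean(effects) - 0.5) < 0.01


def make_two_condition(n_per_group, interaction=0.0, noise_sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("OA", "control"):
        for i in range(n_per_group):
            base = rng.normal(1.0, 0.05)
            for cond in ("habitual", "fast"):
                y = (
                    base
                    + 0.1 * (cond == "fast")
                    + (interaction if (g == "OA" and cond == "fast") else 0.0)
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    dict(
                        participant_id=f"{g}{i}",
                        group=g,
                        gender="F" if i % 2 else "M",
                        condition=cond,
                        walking_speed=rng.normal(1.2, 0.1),
                        y=y,
                    )
                )
    return pd.DataFrame(rows)


class TestInteractionModel:
    def test_null_interaction_small_relative_to_se(self):
        df = make_two_condition(40, interaction=0.0, seed=10)
        res = fit_interaction_model(df, "y")
        assert abs(res.estimate) < 3 * res.se
        assert res.p_raw > 0.001

    def test_recovers_built_in_interaction(self):
        df = make_two_condition(40, interaction=0.3, seed=11)
        res = fit_interaction_model(df, "y")
        assert res.estimate == pytest.approx(0.3, abs=0.05)
        assert res.p_raw < 1e-6

    def test_single_condition_rejected(self):
        df = make_two_condition(10, seed=12)
        with pytest.raises(ValueError):
            fit_interaction_model(df[df.condition == "habitual"], "y")


class TestBH:
    def test_worked_example(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_and_single_value(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.31])[0] == pytest.approx(0.31)

    def test_matches_textbook_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = rng.uniform(0, 1, int(rng.integers(1, 30)))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_null_false_discovery_fraction(self):
        # global null, 19 outcomes, 500 replicates: BH keeps the
        # significant fraction at or below alpha (+2 SE)
        rng = np.random.default_rng(2024)
        flags = []
        for _ in range(500):
            p = rng.uniform(0, 1, 19)
            flags.append(np.any(bh_adjust(p) < 0.05))
        frac = np.mean(flags)
        se = np.sqrt(0.05 * 0.95 / 500)
        assert frac <= 0.05 + 2 * se


class TestICC:
    def test_identical_sessions_give_one(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_3_1(s, s) == pytest.approx(1.0)

    def test_constant_offset_still_one(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_3_1(s, s + 0.7) == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        assert abs(icc_3_1(a, b)) < 0.1

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            icc_3_1([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        truth = rng.normal(0, 1, 30)
        s1 = truth + rng.normal(0, 0.3, 30)
        s2 = truth + rng.normal(0, 0.3, 30) + 0.2
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(30), 2),
                "session": np.repeat(["a", "b"], 30),
                "score": np.concatenate([s1, s2]),
            }
        )
        table = pg.intraclass_corr(
            df, targets="subject", raters="session", ratings="score"
        )
        sel = table.Type.isin(["ICC3", "ICC(C,1)"])  # label varies by version
        want = float(table.loc[sel, "ICC"].iloc[0])
        assert icc_3_1(s1, s2) == pytest.approx(want, abs=1e-9)


def test_compare_outcomes_bh_within_family():
    df = make_records(20, effect=0.3, noise_sd=0.3, seed=42)
    df["z"] = np.random.default_rng(0).standard_normal(len(df))
    table = compare_outcomes(df, ["y", "z"])
    assert set(table.outcome) == {"y", "z"}
    assert (table.p_bh >= table.p_raw - 1e-15).all()
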