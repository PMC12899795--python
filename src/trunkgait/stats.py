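"""Cohort-level statistics for gait-quality outcomes.

Per-outcome group comparisons are ordinary least squares of
``outcome ~ group + gender (+ speed)`` with the control group as the
reference level, so negative estimates mean lower values in the patient
(OA) group. Habitual→fast adaptation differences are tested with linear
mixed-effects models — Group, Condition, their interaction and gender
(plus speed when flagged) as fixed effects, a random intercept per
participant — with the interaction p-value from a likelihood-ratio test
of maximum-likelihood refits. Families of p-values are adjusted with the
Benjamini–Hochberg step-up FDR procedure, and test–retest reliability is
the two-way mixed, consistency, single-measure ICC(3,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, DegenerateSignalError, RankDeficiencyError

GROUP_REFERENCE = "control"   # negative estimates = lower in the OA group


@dataclass
class GroupComparisonResult:
    outcome: str
    estimate: float              # group coefficient (OA minus control)
    se: float
    p_raw: float
    p_bh: float | None = None
    adjusted_for: list[str] = field(default_factory=list)
    n: int = 0


@dataclass
class InteractionResult:
    outcome: str
    estimate: float              # Group x Condition fixed effect
    se: float
    p_raw: float                 # likelihood-ratio test, 1 df
    p_bh: float | None = None
    adjusted_for: list[str] = field(default_factory=list)
    n_participants: int = 0


def _encode(records: pd.DataFrame, col: str, reference: str | None = None):
    """0/1 encoding of a two-level factor; errors name degenerate columns."""
    levels = sorted(records[col].astype(str).unique())
    if len(levels) < 2:
        raise RankDeficiencyError(
            f"factor '{col}' has a single level ({levels[0]}); "
            "its term is collinear with the intercept"
        )
    if len(levels) > 2:
        raise ValueError(f"factor '{col}' has more than two levels: {levels}")
    if reference is not None and reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    return (records[col].astype(str) == levels[1]).astype(float).to_numpy(), levels


def _design(
    records: pd.DataFrame, adjust_speed: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(records))]
    names = ["intercept"]
    g, _ = _encode(records, "group", reference=GROUP_REFERENCE)
    cols.append(g)
    names.append("group")
    s, _ = _encode(records, "gender")
    cols.append(s)
    names.append("gender")
    if adjust_speed:
        cols.append(records["walking_speed"].to_numpy(dtype=float))
        names.append("walking_speed")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank deficient over terms {names}"
        )
    return X, names


def fit_group_model(
    records: pd.DataFrame, outcome: str, adjust_speed: bool = False
) -> GroupComparisonResult:
    """OLS group comparison of one outcome within a single condition.

    ``records`` needs columns group, gender, walking_speed and the outcome;
    requires ≥ 3 records per group and a single condition.
    """
    if "condition" in records.columns and records["condition"].nunique() > 1:
        raise ValueError("fit_group_model expects records from a single condition")
    counts = records.groupby("group")[outcome].count()
    if len(counts) < 2 or counts.min() < 3:
        raise ValueError("need at least 3 records per group")
    X, names = _design(records, adjust_speed)
    y = records[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    i = names.index("group")
    return GroupComparisonResult(
        outcome=outcome,
        estimate=float(fit.params[i]),
        se=float(fit.bse[i]),
        p_raw=float(fit.pvalues[i]),
        adjusted_for=[n for n in names if n not in ("intercept", "group")],
        n=len(records),
    )


def fit_interaction_model(
    records: pd.DataFrame, outcome: str, adjust_speed: bool = False
) -> InteractionResult:
    """Group × Condition mixed model with a random participant intercept.

    Fixed-effect estimates come from the REML fit; the interaction
    p-value from a 1-df likelihood-ratio test of ML refits with and
    without the interaction term.
    """
    for col in ("participant_id", "condition"):
        if col not in records.columns:
            raise ValueError(f"records must carry a '{col}' column")
    conds = sorted(records["condition"].astype(str).unique())
    if len(conds) < 2:
        raise ValueError("both conditions must be present for the interaction model")
    wide = records.pivot_table(
        index="participant_id", columns="condition", values=outcome, aggfunc="size"
    )
    complete = wide.notna().all(axis=1)
    per_group = records[
        records["participant_id"].isin(complete[complete].index)
    ].groupby("group")["participant_id"].nunique()
    if len(per_group) < 2 or per_group.min() < 3:
        raise ValueError(
            "need both conditions for >= 3 participants per group"
        )

    g, _ = _encode(records, "group", reference=GROUP_REFERENCE)
    cond_ref = "habitual" if "habitual" in conds else conds[0]
    treated = [c for c in conds if c != cond_ref][0]
    c = (records["condition"].astype(str) == treated).astype(float).to_numpy()
    s, _ = _encode(records, "gender")
    base = {"intercept": np.ones(len(records)), "group": g, "condition": c,
            "gender": s}
    if adjust_speed:
        base["walking_speed"] = records["walking_speed"].to_numpy(dtype=float)
    inter = g * c

    X_red = pd.DataFrame(base)
    X_full = X_red.assign(group_x_condition=inter)
    y = records[outcome].to_numpy(dtype=float)
    groups = records["participant_id"].to_numpy()

    def _fit(X: pd.DataFrame, reml: bool):
        model = sm.MixedLM(y, X.to_numpy(), groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, "lbfgs", "powell", "cg"):
                try:
                    kwargs = {} if method is None else {"method": method}
                    res = model.fit(reml=reml, **kwargs)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    return res
        raise ConvergenceError(f"mixed model for '{outcome}' did not converge")

    full_reml = _fit(X_full, reml=True)
    full_ml = _fit(X_full, reml=False)
    red_ml = _fit(X_red, reml=False)
    lr = max(0.0, 2.0 * (full_ml.llf - red_ml.llf))
    p = float(sps.chi2.sf(lr, df=1))
    i = list(X_full.columns).index("group_x_condition")
    return InteractionResult(
        outcome=outcome,
        estimate=float(full_reml.fe_params[i]),
        se=float(full_reml.bse_fe[i]),
        p_raw=p,
        adjusted_for=[c for c in X_full.columns
                      if c not in ("intercept", "group", "condition",
                                   "group_x_condition")],
        n_participants=int(records["participant_id"].nunique()),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def icc_3_1(session1, session2) -> float:
    """ICC(3,1): two-way mixed, consistency, single-measure reliability.

    (MS_between − MS_error) / (MS_between + (k−1)·MS_error) with k = 2
    sessions; fixed session offsets are absorbed by the session effect, so
    a constant shift between sessions still yields 1.
    """
    x = np.column_stack([np.asarray(session1, float), np.asarray(session2, float)])
    if not np.isfinite(x).all():
        raise ValueError("sessions contain non-finite values")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    if np.allclose(subj_means.var(), 0.0):
        raise DegenerateSignalError(
            "zero between-subject variance: ICC undefined"
        )
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((subj_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(0.0, ss_total - ss_rows - ss_cols)
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def compare_outcomes(
    records: pd.DataFrame,
    outcomes: list[str],
    adjust_speed: bool = False,
) -> pd.DataFrame:
    """Fit one group model per outcome and BH-adjust within the family."""
    results = [fit_group_model(records, o, adjust_speed) for o in outcomes]
    p_bh = bh_adjust([r.p_raw for r in results])
    rows = []
    for r, adj in zip(results, p_bh):
        r.p_bh = float(adj)
        rows.append(
            {"outcome": r.outcome, "estimate": r.estimate, "se": r.se,
             "p_raw": r.p_raw, "p_bh": r.p_bh, "n": r.n,
             "adjusted_for": "+".join(r.adjusted_for)}
        )
    return pd.DataFrame(rows)


def interaction_table(
    records: pd.DataFrame,
    outcomes: list[str],
    adjust_speed: bool = False,
) -> pd.DataFrame:
    """Fit one interaction model per outcome, BH-adjusted within the family."""
    results = [fit_interaction_model(records, o, adjust_speed) for o in outcomes]
    p_bh = bh_adjust([r.p_raw for r in results])
    rows = []
    for r, adj in zip(results, p_bh):
        r.p_bh = float(adj)
        rows.append(
            {"outcome": r.outcome, "estimate": r.estimate, "se": r.se,
             "p_raw": r.p_raw, "p_bh": r.p_bh,
             "n_participants": r.n_participants,
             "adjusted_for": "+".join(r.adjusted_for)}
        )
    return pd.DataFrame(rows)
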