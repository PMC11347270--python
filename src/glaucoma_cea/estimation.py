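"""Estimate model inputs from individual-level trial data.

Transition probabilities come from a constant-hazard (exponential)
time-to-event analysis of annual per-eye severity records: for each arm and
each adjacent severity pair, ``rate = events / eye-years at risk`` with
actuarial exposure (an eye that progresses during a year contributes half
that year), converted to an annual probability by ``1 - exp(-rate)``.  An
alternative estimator models the annual progression indicator on the logit
scale (intercept-only logistic regression, whose maximum-likelihood fit is
the observed annual proportion); it is selected with ``method='logistic'``.

Annual costs and instrument utilities are fitted by ordinary least squares
on severity-level indicators plus a treatment indicator; the fitted models
extrapolate payoffs to severity/arm cells never observed during follow-up,
which is what lets the model run beyond the trial's horizon.  Costs are
keyed to the worse (more severe) eye, utilities to the better eye.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lifetable import LifeTable
from .params import (
    OUTCOMES,
    ParamSet,
    RegressionModel,
    TransitionEstimate,
    payoff_index,
    prob_to_rate,
    rate_to_prob,
)
from .states import ARM_TRAB, ARMS, SeverityScale, StateSpace, state_name

log = logging.getLogger(__name__)

__all__ = [
    "rate_to_prob",
    "prob_to_rate",
    "estimate_transitions",
    "fit_payoff_regression",
    "estimate_initial_distribution",
    "build_param_set",
    "estimate_params",
]


def _eye_intervals(records: pd.DataFrame, scale: SeverityScale) -> pd.DataFrame:
    """One row per (participant, eye, year->year+1) interval with observed
    states at both ends; censored at death and at unobserved visits."""
    obs = records[records["observed"] & records["alive"]].sort_values(
        ["participant_id", "visit_year"]
    )
    frames = []
    for eye_col in ("index_eye_state", "fellow_eye_state"):
        df = obs[["participant_id", "arm", "visit_year", eye_col]].rename(
            columns={eye_col: "from_level"}
        )
        nxt = df.groupby("participant_id", sort=False)
        to_level = nxt["from_level"].shift(-1)
        to_year = nxt["visit_year"].shift(-1)
        keep = to_year == df["visit_year"] + 1
        sub = df[keep].copy()
        sub["to_level"] = to_level[keep]
        frames.append(sub[["arm", "from_level", "to_level"]])
    return pd.concat(frames, ignore_index=True)


def estimate_transitions(
    records: pd.DataFrame,
    scale: SeverityScale | None = None,
    method: str = "exponential",
) -> dict[tuple[str, str], TransitionEstimate]:
    """Per-arm annual progression probabilities for every adjacent pair.

    Returns a mapping ``(arm, from_level) -> TransitionEstimate``.  A
    transition with zero eye-years at risk raises; a transition with
    exposure but zero events is returned with probability 0 and
    ``wide_uncertainty=True``.
    """
    if method not in ("exponential", "logistic"):
        raise ValueError(f"unknown method {method!r}")
    scale = scale or SeverityScale()
    intervals = _eye_intervals(records, scale)
    out: dict[tuple[str, str], TransitionEstimate] = {}
    for arm in ARMS:
        arm_iv = intervals[intervals["arm"] == arm]
        for frm, to in scale.adjacent_pairs():
            at_risk = arm_iv[arm_iv["from_level"] == frm]
            n = len(at_risk)
            if n == 0:
                raise ValueError(
                    f"zero eye-years at risk for transition {frm}->{to} in arm {arm!r}"
                )
            events = int((at_risk["to_level"] == to).sum())
            if method == "exponential":
                exposure = n - 0.5 * events  # actuarial: events count half a year
                out[(arm, frm)] = TransitionEstimate.from_counts(
                    arm, frm, to, events, exposure
                )
            else:
                p = events / n
                se = float(np.sqrt(p * (1.0 - p) / n))
                out[(arm, frm)] = TransitionEstimate(
                    arm=arm,
                    from_level=frm,
                    to_level=to,
                    annual_probability=p,
                    standard_error=se,
                    events=events,
                    eye_years=float(n),
                    wide_uncertainty=events == 0,
                )
    return out


def _eye_basis(outcome: str) -> str:
    return "worse" if outcome == "annual_cost" else "better"


def _payoff_design(records: pd.DataFrame, outcome: str, scale: SeverityScale):
    rows = records[records["observed"] & records["alive"]]
    idx = rows["index_eye_state"].map(scale.index)
    fel = rows["fellow_eye_state"].map(scale.index)
    lv = np.maximum(idx, fel) if _eye_basis(outcome) == "worse" else np.minimum(idx, fel)
    X = pd.DataFrame({"intercept": 1.0}, index=rows.index)
    for level in scale.levels[1:]:
        X[f"level[{level}]"] = (lv == scale.index(level)).astype(float)
    X["treatment"] = (rows["arm"] == ARM_TRAB).astype(float)
    return X, rows[outcome].astype(float)


def fit_payoff_regression(
    records: pd.DataFrame, outcome: str, scale: SeverityScale | None = None
) -> RegressionModel:
    """OLS of a payoff outcome on severity-level indicators + treatment."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    scale = scale or SeverityScale()
    X, y = _payoff_design(records, outcome, scale)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        empty = [c for c in X.columns if c != "intercept" and X[c].abs().sum() == 0]
        raise ValueError(
            f"rank-deficient design for {outcome}: collinear/empty columns {empty or 'unknown'}"
        )
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    coef = pd.Series(fit.params, index=X.columns)
    cov = pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns)
    return RegressionModel(
        outcome=outcome,
        coefficients=coef,
        covariance=cov,
        eye_basis=_eye_basis(outcome),
        levels=tuple(scale.levels),
    )


def estimate_initial_distribution(
    records: pd.DataFrame, scale: SeverityScale | None = None
) -> pd.Series:
    """Empirical baseline distribution over combined states."""
    scale = scale or SeverityScale()
    space = StateSpace(scale)
    base = records[records["visit_year"] == 0]
    names = [
        state_name(i, f)
        for i, f in zip(base["index_eye_state"], base["fellow_eye_state"])
    ]
    counts = pd.Series(names).value_counts()
    init = pd.Series(0.0, index=pd.Index(space.live_states, name="state"), name="probability")
    init[counts.index] = counts.to_numpy(dtype=float)
    return init / init.sum()


def payoffs_from_regressions(
    regressions: dict[str, RegressionModel],
    scale: SeverityScale,
    coefficient_overrides: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Materialise the (combined state, arm) payoff table from fitted models.

    Utility predictions above 1 are clamped to 1 (and logged); negative cost
    predictions are clamped to 0.
    """
    space = StateSpace(scale)
    overrides = coefficient_overrides or {}
    k = scale.n_levels
    pairs = np.array([(i, f) for i in range(k) for f in range(k)])
    worse, better = pairs.max(axis=1), pairs.min(axis=1)

    index = payoff_index(space)
    arm_is_trab = np.array([arm == ARM_TRAB for (_s, arm) in index])
    columns = {}
    for outcome in OUTCOMES:
        reg = regressions.get(outcome)
        if reg is None:
            raise ValueError(f"missing payoff regression for cell outcome {outcome!r}")
        beta = overrides.get(outcome, reg.coefficients)
        # prediction = intercept + level effect + treatment effect
        level_effect = np.zeros(k)
        for j, lev in enumerate(scale.levels[1:], start=1):
            key = f"level[{lev}]"
            if key not in beta.index:
                raise KeyError(f"level {lev!r} not covered by {outcome} regression")
            level_effect[j] = float(beta[key])
        per_state = float(beta["intercept"]) + level_effect[
            worse if reg.eye_basis == "worse" else better
        ]
        values = np.repeat(per_state, 2)  # two arms per state, trab first
        values = values + arm_is_trab * float(beta["treatment"])
        if outcome == "annual_cost":
            values = np.maximum(values, 0.0)
        else:
            if (values > 1.0).any():
                log.info(
                    "clamping %d %s prediction(s) above 1", int((values > 1.0).sum()), outcome
                )
            values = np.minimum(values, 1.0)
        columns[outcome] = values
    return pd.DataFrame(columns, index=index)


def build_param_set(
    transitions: dict[tuple[str, str], TransitionEstimate],
    regressions: dict[str, RegressionModel],
    life_table: LifeTable,
    initial_distribution: pd.Series,
    scale: SeverityScale | None = None,
    smr_unilateral: float = 1.0,
    smr_bilateral: float = 1.0,
    discount_rate: float = 0.035,
    start_age: int = 65,
    female_fraction: float = 0.3,
) -> ParamSet:
    """Assemble a validated ParamSet from estimated components."""
    scale = scale or SeverityScale()
    payoffs = payoffs_from_regressions(regressions, scale)
    return ParamSet(
        scale=scale,
        transitions=transitions,
        payoffs=payoffs,
        life_table=life_table,
        initial_distribution=initial_distribution,
        smr_unilateral=smr_unilateral,
        smr_bilateral=smr_bilateral,
        discount_rate=discount_rate,
        start_age=start_age,
        female_fraction=female_fraction,
        regressions=regressions,
    )


def estimate_params(
    records: pd.DataFrame,
    life_table: LifeTable,
    scale: SeverityScale | None = None,
    method: str = "exponential",
    smr_unilateral: float = 1.0,
    smr_bilateral: float = 1.0,
    discount_rate: float = 0.035,
    start_age: int = 65,
    female_fraction: float = 0.3,
) -> ParamSet:
    """One-call estimation: transitions, payoff regressions and baseline
    distribution from trial records, assembled into a ParamSet."""
    scale = scale or SeverityScale()
    transitions = estimate_transitions(records, scale, method=method)
    regressions = {o: fit_payoff_regression(records, o, scale) for o in OUTCOMES}
    init = estimate_initial_distribution(records, scale)
    return build_param_set(
        transitions,
        regressions,
        life_table,
        init,
        scale=scale,
        smr_unilateral=smr_unilateral,
        smr_bilateral=smr_bilateral,
        discount_rate=discount_rate,
        start_age=start_age,
        female_fraction=female_fraction,
    )
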