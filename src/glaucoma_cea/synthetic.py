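"""Synthetic two-arm trial generator.

Generates individual-level data with the statistical structure the
estimation stage assumes, so the whole pipeline runs without external data:
two randomized arms (trabeculectomy / medication), participants in their
60s, an index eye with advanced glaucoma at entry, annual visits recording
per-eye severity, a right-skewed annual cost and three utility instruments,
unidirectional progression with arm-specific constant hazards, background
mortality from the shared life-table + SMR machinery, and optional
missingness.

Distributional choices mirror the analysis stage: costs are gamma and
utilities beta, both parameterised by method of moments from (mean, SE);
per-eye annual progression is drawn with probability ``1 - exp(-hazard)``.
The generator is a pure function of its configuration (which includes the
seed): the same config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import LifeTable, make_gompertz_life_table
from .params import ParamSet, TransitionEstimate, payoff_index, rate_to_prob
from .states import (
    ARM_MED,
    ARM_TRAB,
    ARMS,
    SEX_FEMALE,
    SEX_MALE,
    SeverityScale,
    StateSpace,
    state_name,
)

RECORD_COLUMNS = [
    "participant_id",
    "arm",
    "visit_year",
    "index_eye_state",
    "fellow_eye_state",
    "annual_cost",
    "utility_eq5d",
    "utility_hui3",
    "utility_gui",
    "alive",
    "observed",
]

# Default study conditions: a two-arm surgical trial in advanced open angle
# glaucoma.  Surgery slows progression; its annual state costs are higher
# (surgery plus follow-up care vs ongoing medication).  Utilities fall with
# the better eye's severity, more steeply for the vision-sensitive HUI-3 and
# less steeply for the condition-specific GUI.
DEFAULT_HAZARDS = {
    ARM_TRAB: {"advanced": 0.06, "severe": 0.06, "end_stage": 0.05},
    ARM_MED: {"advanced": 0.10, "severe": 0.10, "end_stage": 0.08},
}
DEFAULT_COST_MEAN = {
    ARM_TRAB: (900.0, 1100.0, 1300.0, 1500.0),
    ARM_MED: (600.0, 800.0, 1000.0, 1200.0),
}
DEFAULT_UTILITY_MEAN = {
    "eq5d": (0.80, 0.72, 0.62, 0.48),
    "hui3": (0.78, 0.68, 0.55, 0.38),
    "gui": (0.82, 0.76, 0.70, 0.60),
}


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of the synthetic trial generator.

    All randomness flows from ``rng_seed``; hazards are per-eye annual rates
    keyed ``arm -> from_level``; cost means/SEs are keyed by arm and then by
    the worse eye's severity level; utility means/SEs by instrument and then
    by the better eye's level.
    """

    n_participants: int = 1000
    allocation_ratio: float = 0.5
    baseline_age_mean: float = 67.0
    baseline_age_sd: float = 8.0
    prop_female: float = 0.3
    followup_years: int = 5
    scale: SeverityScale = field(default_factory=SeverityScale)
    index_state_probs: tuple[float, ...] = (0.80, 0.12, 0.05, 0.03)
    fellow_state_probs: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    hazards: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(h) for a, h in DEFAULT_HAZARDS.items()}
    )
    cost_mean: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COST_MEAN)
    )
    cost_se_fraction: float = 0.3
    utility_mean: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_UTILITY_MEAN)
    )
    utility_se: float = 0.12
    smr_unilateral: float = 1.0
    smr_bilateral: float = 1.0
    life_table: LifeTable = field(default_factory=make_gompertz_life_table)
    missingness_prob: float = 0.0
    rng_seed: int = 20240

    def __post_init__(self) -> None:
        k = self.scale.n_levels
        if self.n_participants < 2:
            raise ValueError(f"n_participants must be >= 2, got {self.n_participants}")
        if not 0.0 < self.allocation_ratio < 1.0:
            raise ValueError(f"allocation_ratio must be in (0, 1), got {self.allocation_ratio}")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError(f"prop_female must be in [0, 1], got {self.prop_female}")
        if self.followup_years < 1:
            raise ValueError(f"followup_years must be >= 1, got {self.followup_years}")
        for name, probs in (
            ("index_state_probs", self.index_state_probs),
            ("fellow_state_probs", self.fellow_state_probs),
        ):
            if len(probs) != k:
                raise ValueError(f"{name} must have {k} entries, got {len(probs)}")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for arm in ARMS:
            if arm not in self.hazards:
                raise ValueError(f"hazards missing for arm {arm!r}")
            for frm, to in self.scale.adjacent_pairs():
                if frm not in self.hazards[arm]:
                    raise ValueError(f"hazards missing for transition {frm}->{to} in arm {arm!r}")
                if self.hazards[arm][frm] < 0:
                    raise ValueError(f"hazards[{arm!r}][{frm!r}] must be >= 0")
            if arm not in self.cost_mean or len(self.cost_mean[arm]) != k:
                raise ValueError(f"cost_mean[{arm!r}] must have {k} entries")
            if any(c <= 0 for c in self.cost_mean[arm]):
                raise ValueError(f"cost_mean[{arm!r}] entries must be > 0")
        for inst, means in self.utility_mean.items():
            if len(means) != k:
                raise ValueError(f"utility_mean[{inst!r}] must have {k} entries")
            for m in means:
                if not 0.0 <= m <= 1.0:
                    raise ValueError(f"utility_mean[{inst!r}] entries must be in [0, 1]")
                if 0.0 < m < 1.0 and self.utility_se**2 >= m * (1.0 - m):
                    raise ValueError(
                        f"utility_se too large for beta with mean {m} (utility_mean[{inst!r}])"
                    )
        if not 0.0 <= self.missingness_prob < 1.0:
            raise ValueError(
                f"missingness_prob must be in [0, 1), got {self.missingness_prob}"
            )
        if self.smr_unilateral < 1 or self.smr_bilateral < 1:
            raise ValueError("smr_unilateral and smr_bilateral must be >= 1")

    def with_updates(self, **kwargs) -> "TrialConfig":
        return replace(self, **kwargs)


def _stage_rng(config: TrialConfig, stage: int) -> np.random.Generator:
    # one deterministic child stream per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.rng_seed), stage]))


def _draw_gamma(rng, mean: np.ndarray, se: np.ndarray) -> np.ndarray:
    out = np.asarray(mean, dtype=float).copy()
    stochastic = se > 0
    if stochastic.any():
        shape = mean[stochastic] ** 2 / se[stochastic] ** 2
        scale = se[stochastic] ** 2 / mean[stochastic]
        out[stochastic] = rng.gamma(shape, scale)
    return out


def _draw_beta(rng, mean: np.ndarray, se: np.ndarray) -> np.ndarray:
    out = np.asarray(mean, dtype=float).copy()
    interior = (se > 0) & (mean > 0) & (mean < 1)
    if interior.any():
        m = mean[interior]
        nu = m * (1.0 - m) / se[interior] ** 2 - 1.0
        out[interior] = rng.beta(m * nu, (1.0 - m) * nu)
    return out


def generate_cohort(config: TrialConfig) -> pd.DataFrame:
    """Baseline cohort: id, arm, age, sex and per-eye entry states.

    Arm sizes are exact (``round(n * allocation_ratio)`` to trabeculectomy)
    with randomized order.  The index eye's entry level is drawn from
    ``index_state_probs`` (every scale level is at or beyond advanced
    disease, so the index eye always qualifies); the fellow eye is the more
    severe of the index level and a draw from ``fellow_state_probs``, so the
    index eye is the less severe eligible eye by construction, mirroring a
    trial that treats the better-preserved eye first.
    """
    rng = _stage_rng(config, 0)
    n = config.n_participants
    n_trab = int(round(n * config.allocation_ratio))
    arms = np.array([ARM_TRAB] * n_trab + [ARM_MED] * (n - n_trab))
    rng.shuffle(arms)

    lt = config.life_table
    lo, hi = lt.min_age, lt.terminal_age - 1
    ages = np.clip(
        np.round(rng.normal(config.baseline_age_mean, config.baseline_age_sd, size=n)),
        lo,
        hi,
    ).astype(int)
    sexes = np.where(rng.random(n) < config.prop_female, SEX_FEMALE, SEX_MALE)

    k = config.scale.n_levels
    index_lv = rng.choice(k, size=n, p=np.asarray(config.index_state_probs, dtype=float))
    eye_b = rng.choice(k, size=n, p=np.asarray(config.fellow_state_probs, dtype=float))
    fellow_lv = np.maximum(index_lv, eye_b)

    levels = np.array(config.scale.levels)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "arm": arms,
            "age": ages,
            "sex": sexes,
            "index_eye_state": levels[index_lv],
            "fellow_eye_state": levels[fellow_lv],
        }
    )


def simulate_followup(cohort: pd.DataFrame, config: TrialConfig) -> pd.DataFrame:
    """Annual visit records for every participant from baseline to follow-up end.

    Each year, per-eye progression is drawn with probability
    ``1 - exp(-hazard)`` (no level skipping), death with the life-table
    probability at current age adjusted by the blindness SMRs, the annual
    cost from a gamma and the three utilities from betas parameterised by
    method of moments.  A participant who dies contributes one final record
    with ``alive = False`` (zero cost and utilities, states frozen) in the
    year of death, then exits.
    """
    rng = _stage_rng(config, 1)
    scale = config.scale
    k = scale.n_levels
    n = len(cohort)
    levels = np.array(scale.levels)
    blind = k - 1

    # per-(arm, level) transition probability, last level absorbing
    p_prog = {}
    for arm in ARMS:
        p = np.zeros(k)
        for i, lev in enumerate(scale.levels[:-1]):
            p[i] = -np.expm1(-config.hazards[arm][lev])
        p_prog[arm] = p

    cost_mean = {a: np.asarray(config.cost_mean[a], dtype=float) for a in ARMS}
    util_mean = {i: np.asarray(m, dtype=float) for i, m in config.utility_mean.items()}

    arm_is_trab = (cohort["arm"] == ARM_TRAB).to_numpy()
    ages0 = cohort["age"].to_numpy()
    is_female = (cohort["sex"] == SEX_FEMALE).to_numpy()
    idx = np.array([scale.index(s) for s in cohort["index_eye_state"]])
    fel = np.array([scale.index(s) for s in cohort["fellow_eye_state"]])
    alive = np.ones(n, dtype=bool)
    ids = cohort["participant_id"].to_numpy()
    arms_arr = cohort["arm"].to_numpy()

    lt = config.life_table
    q_by_age = {
        sex: {a: lt.qx(a, sex) for a in range(lt.min_age, lt.terminal_age + 1)}
        for sex in (SEX_MALE, SEX_FEMALE)
    }

    frames = []
    died_this_year = np.zeros(n, dtype=bool)
    for year in range(config.followup_years + 1):
        emit = alive | died_this_year
        m = int(emit.sum())
        if m == 0:
            break
        worse = np.maximum(idx, fel)[emit]
        better = np.minimum(idx, fel)[emit]
        live_mask = alive[emit]

        costs = np.zeros(m)
        utils = {i: np.zeros(m) for i in util_mean}
        if live_mask.any():
            cm = np.where(
                arm_is_trab[emit],
                cost_mean[ARM_TRAB][worse],
                cost_mean[ARM_MED][worse],
            )
            costs_live = _draw_gamma(
                rng, cm[live_mask], config.cost_se_fraction * cm[live_mask]
            )
            costs[live_mask] = costs_live
            for inst in util_mean:
                um = util_mean[inst][better]
                se = np.full(live_mask.sum(), config.utility_se)
                utils[inst][live_mask] = _draw_beta(rng, um[live_mask], se)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ids[emit],
                    "arm": arms_arr[emit],
                    "visit_year": year,
                    "index_eye_state": levels[idx[emit]],
                    "fellow_eye_state": levels[fel[emit]],
                    "annual_cost": costs,
                    "utility_eq5d": utils["eq5d"],
                    "utility_hui3": utils["hui3"],
                    "utility_gui": utils["gui"],
                    "alive": live_mask,
                    "observed": True,
                }
            )
        )
        died_this_year[:] = False
        if year == config.followup_years:
            break

        # mortality first (competing risk), then progression among survivors
        age_now = ages0 + year
        q = np.array(
            [
                q_by_age[SEX_FEMALE if f else SEX_MALE].get(a, 1.0)
                for f, a in zip(is_female, age_now)
            ]
        )
        n_blind = (idx == blind).astype(int) + (fel == blind).astype(int)
        smr = np.choose(n_blind, [1.0, config.smr_unilateral, config.smr_bilateral])
        q_adj = 1.0 - (1.0 - q) ** smr
        dies = alive & (rng.random(n) < q_adj)
        died_this_year = dies
        alive = alive & ~dies

        p_i = np.where(arm_is_trab, p_prog[ARM_TRAB][idx], p_prog[ARM_MED][idx])
        p_f = np.where(arm_is_trab, p_prog[ARM_TRAB][fel], p_prog[ARM_MED][fel])
        adv_i = alive & (rng.random(n) < p_i)
        adv_f = alive & (rng.random(n) < p_f)
        idx = np.minimum(idx + adv_i, blind)
        fel = np.minimum(fel + adv_f, blind)

    records = pd.concat(frames, ignore_index=True)
    return records[RECORD_COLUMNS]


def apply_missingness(
    records: pd.DataFrame, missingness_prob: float, seed: int
) -> pd.DataFrame:
    """Independently mask post-baseline records; baseline is never masked."""
    if not 0.0 <= missingness_prob < 1.0:
        raise ValueError(f"missingness_prob must be in [0, 1), got {missingness_prob}")
    out = records.copy()
    if missingness_prob == 0.0:
        out["observed"] = True
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    maskable = (out["visit_year"] > 0).to_numpy()
    draws = rng.random(len(out))
    out["observed"] = ~(maskable & (draws < missingness_prob))
    return out


def generate_trial(config: TrialConfig) -> pd.DataFrame:
    """Full generator: cohort, follow-up and (optional) missingness."""
    cohort = generate_cohort(config)
    records = simulate_followup(cohort, config)
    if config.missingness_prob > 0:
        records = apply_missingness(records, config.missingness_prob, config.rng_seed)
    return records


# ---------------------------------------------------------------------- io

_NUMERIC = ["annual_cost", "utility_eq5d", "utility_hui3", "utility_gui"]


def write_trial(records: pd.DataFrame, path) -> None:
    """Write visit records as CSV; rejects non-finite numeric values."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    for col in _NUMERIC:
        vals = records[col].to_numpy(dtype=float)
        if len(vals) and not np.isfinite(vals).all():
            raise ValueError(f"non-finite value in column {col!r}")
    records[RECORD_COLUMNS].to_csv(Path(path), index=False)


def read_trial(path) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path),
        dtype={
            "participant_id": int,
            "arm": str,
            "visit_year": int,
            "index_eye_state": str,
            "fellow_eye_state": str,
            "alive": bool,
            "observed": bool,
        },
    )
    return df[RECORD_COLUMNS]


# ------------------------------------------------- truth-value ParamSet


def truth_param_set(config: TrialConfig, discount_rate: float = 0.035) -> ParamSet:
    """ParamSet built from the generator's true parameters (no estimation).

    Useful as ground truth in parameter-recovery checks and for running the
    model at exactly the conditions the generator encodes.
    """
    scale = config.scale
    space = StateSpace(scale)
    transitions = {}
    for arm in ARMS:
        for frm, to in scale.adjacent_pairs():
            transitions[(arm, frm)] = TransitionEstimate(
                arm=arm,
                from_level=frm,
                to_level=to,
                annual_probability=rate_to_prob(config.hazards[arm][frm]),
            )
    rows = []
    for state in space.live_states:
        i, f = space.levels_of(state)
        worse, better = max(i, f), min(i, f)
        for arm in ARMS:
            rows.append(
                {
                    "state": state,
                    "arm": arm,
                    "annual_cost": config.cost_mean[arm][worse],
                    "utility_eq5d": config.utility_mean["eq5d"][better],
                    "utility_hui3": config.utility_mean["hui3"][better],
                    "utility_gui": config.utility_mean["gui"][better],
                }
            )
    payoffs = pd.DataFrame(rows).set_index(["state", "arm"])
    payoffs = payoffs.reindex(payoff_index(space))

    # entry model: index ~ index_state_probs, fellow = max(index, draw)
    p_idx = np.asarray(config.index_state_probs, dtype=float)
    p_fel = np.asarray(config.fellow_state_probs, dtype=float)
    init = pd.Series(
        0.0, index=pd.Index(space.live_states, name="state"), name="probability"
    )
    k = scale.n_levels
    for i in range(k):
        for j in range(i, k):
            mass = p_fel[: i + 1].sum() if j == i else p_fel[j]
            init[state_name(scale.levels[i], scale.levels[j])] += p_idx[i] * mass

    return ParamSet(
        scale=scale,
        transitions=transitions,
        payoffs=payoffs,
        life_table=config.life_table,
        initial_distribution=init,
        smr_unilateral=config.smr_unilateral,
        smr_bilateral=config.smr_bilateral,
        discount_rate=discount_rate,
        start_age=int(round(config.baseline_age_mean)),
        female_fraction=config.prop_female,
    )
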