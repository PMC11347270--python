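"""Two-eye Markov cohort engine.

Builds annual transition matrices over the combined state space and runs
cohort traces to an arbitrary (or lifetime) horizon.  Within a cycle the
competing-risk convention is: death first — with the life-table probability
at the cohort's current age, adjusted by the blindness SMRs — then, among
survivors, each eye independently either stays or moves one level worse
with its arm-specific annual probability.  Joint two-eye moves therefore
carry the product of the per-eye probabilities, no level is ever skipped,
and no mass flows towards less severe states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParamSet
from .states import DEATH, SEX_FEMALE, SEX_MALE, StateSpace

ROW_SUM_TOL = 1e-9


def adjust_mortality(
    q: float, n_blind_eyes: int, smr_unilateral: float, smr_bilateral: float
) -> float:
    """Blindness-adjusted annual death probability: ``1 - (1-q)**SMR``.

    The SMR acts on the survival probability (equivalently, it multiplies
    the mortality hazard), so the result stays in [0, 1] for any SMR >= 1.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if smr_unilateral < 1.0 or smr_bilateral < 1.0:
        raise ValueError("SMR < 1 (reduced mortality) is not supported")
    if n_blind_eyes not in (0, 1, 2):
        raise ValueError(f"n_blind_eyes must be 0, 1 or 2, got {n_blind_eyes}")
    smr = (1.0, smr_unilateral, smr_bilateral)[n_blind_eyes]
    return 1.0 - (1.0 - q) ** smr


def _progression_block(param_set: ParamSet, arm: str) -> np.ndarray:
    """Conditional (survivors-only) progression matrix over live states."""
    space = param_set.space
    k = param_set.scale.n_levels
    n_live = space.n_live
    p_level = np.array(
        [param_set.annual_progression(arm, lev) for lev in param_set.scale.levels]
    )
    block = np.zeros((n_live, n_live))
    for s in range(n_live):
        i, f = divmod(s, k)
        pi, pf = p_level[i], p_level[f]
        for di in (0, 1):
            if di == 1 and i == k - 1:
                continue
            for df in (0, 1):
                if df == 1 and f == k - 1:
                    continue
                w = (pi if di else 1.0 - pi) * (pf if df else 1.0 - pf)
                block[s, (i + di) * k + (f + df)] += w
    return block


def _smr_exponents(param_set: ParamSet) -> np.ndarray:
    """Per-live-state SMR exponent (1, unilateral or bilateral)."""
    space = param_set.space
    n_blind = np.array([space.n_blind_eyes(s) for s in space.live_states])
    if param_set.smr_unilateral < 1.0 or param_set.smr_bilateral < 1.0:
        raise ValueError("SMR < 1 (reduced mortality) is not supported")
    return np.choose(
        n_blind, [1.0, param_set.smr_unilateral, param_set.smr_bilateral]
    )


def _adjusted_death(param_set: ParamSet, q: float, smr: np.ndarray | None = None) -> np.ndarray:
    """Per-live-state death probability after the blindness SMR adjustment."""
    if smr is None:
        smr = _smr_exponents(param_set)
    return 1.0 - (1.0 - q) ** smr


def _mixed_q(param_set: ParamSet, age: int, sex) -> float:
    if sex == SEX_MALE or sex == SEX_FEMALE:
        return param_set.life_table.qx(age, sex)
    if sex is None or sex == "mixed":
        return param_set.life_table.mixed_qx(age, param_set.female_fraction)
    if isinstance(sex, (int, float)):
        return param_set.life_table.mixed_qx(age, float(sex))
    raise ValueError(f"sex must be 'male', 'female', 'mixed' or a female fraction, got {sex!r}")


def build_transition_matrix(
    param_set: ParamSet, arm: str, age: int, sex="mixed"
) -> pd.DataFrame:
    """Annual transition matrix over all combined states for one arm/age/sex.

    ``sex`` may be 'male', 'female', 'mixed' (uses the ParamSet's female
    fraction) or an explicit female fraction in [0, 1].
    """
    space = param_set.space
    q = _mixed_q(param_set, age, sex)
    q_adj = _adjusted_death(param_set, q)
    block = _progression_block(param_set, arm)
    n = space.n_states
    mat = np.zeros((n, n))
    mat[: space.n_live, : space.n_live] = (1.0 - q_adj)[:, None] * block
    mat[: space.n_live, -1] = q_adj
    mat[-1, -1] = 1.0
    _check_rows(mat, space)
    return pd.DataFrame(mat, index=space.states, columns=space.states)


def _check_rows(mat: np.ndarray, space: StateSpace) -> None:
    sums = mat.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_SUM_TOL
    if bad.any():
        which = space.states[int(np.argmax(bad))]
        raise ValueError(
            f"transition matrix row for state {which!r} sums to {sums[bad][0]!r}"
        )


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy probabilities by cycle, with the cohort profile.

    ``occupancy`` has one row per cycle (year) from 0 to the horizon and one
    column per combined state (death last).  Every row sums to 1 and death
    occupancy is non-decreasing.
    """

    occupancy: pd.DataFrame
    arm: str
    start_age: int
    female_fraction: float

    def __post_init__(self) -> None:
        occ = self.occupancy.to_numpy()
        if np.abs(occ.sum(axis=1) - 1.0).max() > ROW_SUM_TOL * occ.shape[0]:
            raise ValueError("cohort trace rows do not sum to 1")
        dead = self.occupancy[DEATH].to_numpy()
        if (np.diff(dead) < -1e-12).any():
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return len(self.occupancy) - 1

    def write(self, path) -> None:
        self.occupancy.rename_axis("cycle").to_csv(path)


def lifetime_horizon(param_set: ParamSet, start_age: int | None = None) -> int:
    """Cycles from the start age to (and including) the terminal-age cycle."""
    start = param_set.start_age if start_age is None else start_age
    return param_set.life_table.terminal_age - start + 1


def run_cohort(
    param_set: ParamSet,
    arm: str,
    horizon_years: int | None = None,
    start_age: int | None = None,
    female_fraction: float | None = None,
) -> CohortTrace:
    """Run the annual-cycle cohort trace for one arm.

    ``horizon_years=None`` means lifetime: the trace runs until the life
    table's terminal age (where qx = 1 guarantees full absorption into
    death).  Matrices are rebuilt each cycle as the cohort ages; sexes are
    mixed by weighted average of the life-table death probabilities.
    """
    space = param_set.space
    start = param_set.start_age if start_age is None else start_age
    ff = param_set.female_fraction if female_fraction is None else female_fraction
    horizon = lifetime_horizon(param_set, start) if horizon_years is None else int(horizon_years)
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")

    init = param_set.initial_distribution.reindex(space.live_states).fillna(0.0)
    row = np.zeros(space.n_states)
    row[: space.n_live] = init.to_numpy()
    block = {a: _progression_block(param_set, a) for a in (arm,)}[arm]

    smr = _smr_exponents(param_set)
    qs = param_set.life_table.mixed_qx_path(start, horizon, ff)
    rows = [row.copy()]
    for t in range(horizon):
        q_adj = _adjusted_death(param_set, qs[t], smr)
        live = row[: space.n_live]
        survivors = live * (1.0 - q_adj)
        new_dead = row[-1] + float((live * q_adj).sum())
        nxt = np.empty_like(row)
        nxt[: space.n_live] = survivors @ block
        nxt[-1] = new_dead
        row = nxt
        rows.append(row.copy())

    occupancy = pd.DataFrame(
        np.vstack(rows), columns=space.states, index=pd.RangeIndex(horizon + 1, name="cycle")
    )
    return CohortTrace(
        occupancy=occupancy, arm=arm, start_age=start, female_fraction=ff
    )
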