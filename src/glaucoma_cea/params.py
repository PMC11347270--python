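"""Model parameter containers: transitions, payoffs, and the full ParamSet.

A :class:`ParamSet` is everything one deterministic model run needs:
per-arm annual progression probabilities for each adjacent severity pair,
an annual cost and three instrument utilities for every live combined state
and arm, standardised mortality ratios for unilateral/bilateral blindness,
the discount rate, the life table, the initial distribution over combined
states, and the cohort age/sex profile.  It round-trips losslessly to a
directory of delimited-text files plus a YAML settings file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lifetable import LifeTable
from .states import ARMS, SeverityScale, StateSpace

OUTCOMES = ("annual_cost", "utility_eq5d", "utility_hui3", "utility_gui")
UTILITY_OUTCOMES = OUTCOMES[1:]
INSTRUMENTS = ("eq5d", "hui3", "gui")


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Convert a constant hazard rate to the probability of an event in ``t`` years.

    Standard actuarial conversion ``p = 1 - exp(-rate * t)``.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return -math.expm1(-rate * t)


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Exact inverse of :func:`rate_to_prob`: ``rate = -ln(1 - p) / t``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return -math.log1p(-p) / t


@dataclass(frozen=True)
class TransitionEstimate:
    """Annual probability of one adjacent severity progression in one arm.

    ``annual_probability`` and ``underlying_rate`` are linked by
    ``p = 1 - exp(-rate)``; ``standard_error`` is on the probability scale.
    ``wide_uncertainty`` flags zero-event estimates whose uncertainty the
    data cannot bound.
    """

    arm: str
    from_level: str
    to_level: str
    annual_probability: float
    standard_error: float = 0.0
    events: float = float("nan")
    eye_years: float = float("nan")
    wide_uncertainty: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_probability <= 1.0:
            raise ValueError(
                f"annual_probability out of [0,1] for {self.arm} "
                f"{self.from_level}->{self.to_level}: {self.annual_probability}"
            )

    @property
    def underlying_rate(self) -> float:
        return prob_to_rate(min(self.annual_probability, 1.0 - 1e-15))

    @classmethod
    def from_counts(
        cls, arm: str, from_level: str, to_level: str, events: float, eye_years: float
    ) -> "TransitionEstimate":
        """Exponential estimate from an event count and continuous exposure.

        rate = events / eye-years; p = 1 - exp(-rate); SE from the
        square-root-of-events rule on the rate scale, propagated through the
        exponential map (delta method).
        """
        if eye_years <= 0:
            raise ValueError(
                f"zero eye-years at risk for transition {arm} {from_level}->{to_level}"
            )
        rate = events / eye_years
        p = rate_to_prob(rate)
        if events > 0:
            se_rate = math.sqrt(events) / eye_years
            se_p = math.exp(-rate) * se_rate
            wide = False
        else:
            se_p = 0.0
            wide = True
        return cls(
            arm=arm,
            from_level=from_level,
            to_level=to_level,
            annual_probability=p,
            standard_error=se_p,
            events=events,
            eye_years=eye_years,
            wide_uncertainty=wide,
        )


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of a payoff outcome on severity level and treatment arm.

    ``coefficients`` holds intercept + severity-level effects (relative to the
    least severe level) + a treatment indicator; ``covariance`` is their
    sampling covariance, used for multinormal draws in the PSA.
    ``eye_basis`` records which eye's level the outcome is keyed to:
    'worse' for costs (treatment intensity follows the worse eye) and
    'better' for utilities (vision-related quality of life follows the
    better eye).
    """

    outcome: str
    coefficients: pd.Series
    covariance: pd.DataFrame
    eye_basis: str  # 'worse' | 'better'
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.eye_basis not in ("worse", "better"):
            raise ValueError("eye_basis must be 'worse' or 'better'")
        cov = self.covariance.to_numpy()
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError(f"covariance for {self.outcome} is not symmetric")
        if (np.diag(cov) < -1e-12).any():
            raise ValueError(f"covariance for {self.outcome} has negative variance")

    def predict(self, level: str, arm: str, coefficients: pd.Series | None = None) -> float:
        """Model prediction for a severity level and arm (extrapolates to
        unobserved cells; utility predictions are clamped to <= 1 by the
        payoff builder, not here)."""
        beta = self.coefficients if coefficients is None else coefficients
        value = float(beta["intercept"])
        key = f"level[{level}]"
        if key in beta.index:
            value += float(beta[key])
        elif level != self.levels[0]:
            raise KeyError(f"level {level!r} not covered by {self.outcome} regression")
        from .states import ARM_TRAB

        if arm == ARM_TRAB:
            value += float(beta["treatment"])
        return value


def payoff_index(space: StateSpace) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [space.live_states, list(ARMS)], names=["state", "arm"]
    )


@dataclass(frozen=True)
class ParamSet:
    """Complete parameter set for one model run.

    Attributes
    ----------
    scale
        Per-eye severity scale.
    transitions
        Mapping ``(arm, from_level) -> TransitionEstimate`` covering every
        adjacent pair in both arms.
    payoffs
        DataFrame indexed by (combined state, arm) with columns
        ``annual_cost, utility_eq5d, utility_hui3, utility_gui``.
    smr_unilateral, smr_bilateral
        Standardised mortality ratios (>= 1) applied to the life-table death
        probability when one / both eyes are blind.
    discount_rate
        Annual discount rate for costs and QALYs (UK reference 3.5%).
    life_table
        Background all-cause mortality.
    initial_distribution
        Probabilities over live combined states at model entry.
    start_age, female_fraction
        Cohort profile: single starting age, mixing over sex by weighted
        average of qx.
    regressions
        Optional fitted payoff regressions (kept for PSA coefficient draws).
    cost_scale, utility_scale
        Multipliers (base 1.0) applied to payoff columns at matrix/accrual
        time; exposed so deterministic sensitivity analysis can shift whole
        cost or utility schedules.
    """

    scale: SeverityScale
    transitions: dict[tuple[str, str], TransitionEstimate]
    payoffs: pd.DataFrame
    life_table: LifeTable
    initial_distribution: pd.Series
    smr_unilateral: float = 1.0
    smr_bilateral: float = 1.0
    discount_rate: float = 0.035
    start_age: int = 65
    female_fraction: float = 0.3
    regressions: dict[str, RegressionModel] | None = None
    cost_scale: float = 1.0
    utility_scale: dict[str, float] = field(
        default_factory=lambda: {i: 1.0 for i in INSTRUMENTS}
    )

    def __post_init__(self) -> None:
        space = self.space
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.smr_unilateral < 1 or self.smr_bilateral < 1:
            raise ValueError("SMRs < 1 (reduced mortality) are not supported")
        for arm in ARMS:
            for frm, to in self.scale.adjacent_pairs():
                if (arm, frm) not in self.transitions:
                    raise ValueError(
                        f"transition missing for reachable pair {frm}->{to} in arm {arm!r}"
                    )
        missing = [
            (s, a)
            for s in space.live_states
            for a in ARMS
            if (s, a) not in self.payoffs.index
        ]
        if missing:
            raise ValueError(f"payoff rows missing for state/arm cells: {missing[:4]} ...")
        for col in OUTCOMES:
            if col not in self.payoffs.columns:
                raise ValueError(f"payoff table missing column {col!r}")
        if (self.payoffs["annual_cost"] < 0).any():
            raise ValueError("negative annual_cost in payoff table")
        for col in UTILITY_OUTCOMES:
            if (self.payoffs[col] > 1 + 1e-9).any():
                raise ValueError(f"{col} above 1 in payoff table")
        init = self.initial_distribution
        if abs(float(init.sum()) - 1.0) > 1e-9 or (init < -1e-12).any():
            raise ValueError("initial_distribution must be a probability vector over live states")
        unknown = [s for s in init.index if s not in space.live_states]
        if unknown:
            raise ValueError(f"initial_distribution has unknown states: {unknown}")

    @property
    def space(self) -> StateSpace:
        return StateSpace(self.scale)

    def annual_progression(self, arm: str, from_level: str) -> float:
        """Per-cycle probability the eye progresses one level (0 at blind)."""
        if self.scale.successor(from_level) is None:
            return 0.0
        return self.transitions[(arm, from_level)].annual_probability

    def with_updates(self, **kwargs) -> "ParamSet":
        return replace(self, **kwargs)

    # ------------------------------------------------------------------ io

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "arm": t.arm,
                "from_level": t.from_level,
                "to_level": t.to_level,
                "annual_probability": t.annual_probability,
                "standard_error": t.standard_error,
                "events": t.events,
                "eye_years": t.eye_years,
                "wide_uncertainty": t.wide_uncertainty,
            }
            for t in self.transitions.values()
        ]
        pd.DataFrame(rows).to_csv(d / "transitions.csv", index=False)
        self.payoffs.reset_index().to_csv(d / "payoffs.csv", index=False)
        self.life_table.write(d / "life_table.csv")
        self.initial_distribution.rename("probability").rename_axis("state").reset_index().to_csv(
            d / "initial_distribution.csv", index=False
        )
        settings = {
            "severity_levels": list(self.scale.levels),
            "smr_unilateral": float(self.smr_unilateral),
            "smr_bilateral": float(self.smr_bilateral),
            "discount_rate": float(self.discount_rate),
            "start_age": int(self.start_age),
            "female_fraction": float(self.female_fraction),
        }
        with open(d / "settings.yaml", "w") as fh:
            yaml.safe_dump(settings, fh)
        if self.regressions:
            for name, reg in self.regressions.items():
                coef = reg.coefficients.rename("estimate").rename_axis("term").reset_index()
                coef.to_csv(d / f"regression_{name}_coef.csv", index=False)
                reg.covariance.rename_axis("term").reset_index().to_csv(
                    d / f"regression_{name}_cov.csv", index=False
                )
            meta = {
                name: {"eye_basis": reg.eye_basis, "levels": list(reg.levels)}
                for name, reg in self.regressions.items()
            }
            with open(d / "regressions.yaml", "w") as fh:
                yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory) -> "ParamSet":
        d = Path(directory)
        with open(d / "settings.yaml") as fh:
            settings = yaml.safe_load(fh)
        scale = SeverityScale(tuple(settings["severity_levels"]))
        tr = pd.read_csv(d / "transitions.csv")
        transitions = {
            (r.arm, r.from_level): TransitionEstimate(
                arm=r.arm,
                from_level=r.from_level,
                to_level=r.to_level,
                annual_probability=r.annual_probability,
                standard_error=r.standard_error,
                events=r.events,
                eye_years=r.eye_years,
                wide_uncertainty=bool(r.wide_uncertainty),
            )
            for r in tr.itertuples()
        }
        payoffs = pd.read_csv(d / "payoffs.csv").set_index(["state", "arm"])
        init = pd.read_csv(d / "initial_distribution.csv").set_index("state")["probability"]
        regressions = None
        if (d / "regressions.yaml").exists():
            with open(d / "regressions.yaml") as fh:
                meta = yaml.safe_load(fh)
            regressions = {}
            for name, m in meta.items():
                coef = pd.read_csv(d / f"regression_{name}_coef.csv").set_index("term")["estimate"]
                cov = pd.read_csv(d / f"regression_{name}_cov.csv").set_index("term")
                regressions[name] = RegressionModel(
                    outcome=name,
                    coefficients=coef,
                    covariance=cov,
                    eye_basis=m["eye_basis"],
                    levels=tuple(m["levels"]),
                )
        return cls(
            scale=scale,
            transitions=transitions,
            payoffs=payoffs,
            life_table=LifeTable.read(d / "life_table.csv"),
            initial_distribution=init,
            smr_unilateral=settings["smr_unilateral"],
            smr_bilateral=settings["smr_bilateral"],
            discount_rate=settings["discount_rate"],
            start_age=settings["start_age"],
            female_fraction=settings["female_fraction"],
            regressions=regressions,
        )
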