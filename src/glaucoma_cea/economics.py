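"""Discounted costs, QALYs, ICERs and net monetary benefit.

QALYs are accumulated by multiplying the time the cohort spends in each
health state by that state's utility; costs likewise with annual state
costs.  Both are discounted at an annual rate (UK reference 3.5%).  By
default payoffs accrue at cycle start (occupancy row ``t`` weighted by
``(1+d)**-t``); an optional half-cycle correction instead weights the
average of adjacent occupancy rows, approximating mid-cycle events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace
from .params import ParamSet

DEFAULT_THRESHOLDS = (0.0, 10_000.0, 20_000.0, 50_000.0)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate and accrual convention."""

    rate: float = 0.035
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.rate}")


def discount_factor(t: float, spec: DiscountSpec | float) -> float:
    """Present-value factor ``(1+d)**-t`` for year ``t``."""
    d = spec.rate if isinstance(spec, DiscountSpec) else float(spec)
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return (1.0 + d) ** (-t)


@dataclass(frozen=True)
class EconResult:
    """Discounted totals for one arm, instrument and horizon."""

    arm: str
    instrument: str
    horizon: int | str
    cost: float
    qalys: float


def _payoff_vectors(param_set: ParamSet, arm: str, instrument: str):
    space = param_set.space
    sub = param_set.payoffs.xs(arm, level="arm").reindex(space.live_states)
    cost = sub["annual_cost"].to_numpy() * param_set.cost_scale
    scale = param_set.utility_scale.get(instrument, 1.0)
    util = np.minimum(sub[f"utility_{instrument}"].to_numpy() * scale, 1.0)
    return cost, util


def accumulate(
    trace: CohortTrace,
    param_set: ParamSet,
    instrument: str = "eq5d",
    spec: DiscountSpec | None = None,
    horizon: int | None = None,
) -> EconResult:
    """Discounted cost and QALY totals over ``horizon`` annual cycles.

    The death state contributes nothing.  ``horizon`` defaults to the full
    trace; it counts accrual cycles, so a 2-year horizon sums cycles 0 and 1.
    """
    spec = spec or DiscountSpec(param_set.discount_rate)
    n_cycles = trace.n_cycles
    horizon = n_cycles if horizon is None else int(horizon)
    if horizon > n_cycles:
        raise ValueError(f"horizon {horizon} exceeds trace length {n_cycles}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    cost_vec, util_vec = _payoff_vectors(param_set, trace.arm, instrument)
    occ = trace.occupancy.to_numpy()[:, : param_set.space.n_live]
    if spec.half_cycle_correction:
        weights = 0.5 * (occ[:horizon] + occ[1 : horizon + 1])
    else:
        weights = occ[:horizon]
    factors = (1.0 + spec.rate) ** (-np.arange(horizon))
    cost = float(factors @ (weights @ cost_vec))
    qalys = float(factors @ (weights @ util_vec))
    return EconResult(
        arm=trace.arm, instrument=instrument, horizon=horizon, cost=cost, qalys=qalys
    )


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio or a dominance verdict.

    Returns the ratio when defined, ``'dominant'`` (cheaper and more
    effective), ``'dominated'`` (costlier and less effective) or
    ``'undefined'`` when the QALY difference is zero.
    """
    if delta_qaly == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    return delta_cost / delta_qaly


def nmb(cost: float, qalys: float, threshold: float) -> float:
    """Net monetary benefit ``lambda * QALYs - cost`` at willingness-to-pay."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return threshold * qalys - cost


TABLE_COLUMNS = ["Cost", "dCost", "QALY", "dQALY", "ICER", "NMB"]


def incremental_table(
    results: dict[tuple, EconResult],
    thresholds=DEFAULT_THRESHOLDS,
    nmb_threshold: float = 20_000.0,
    ce_probabilities: dict[tuple, dict[float, float]] | None = None,
) -> pd.DataFrame:
    """Table-1-style incremental comparison: trabeculectomy minus medication.

    ``results`` maps ``(horizon label, instrument, arm)`` to an EconResult;
    ``ce_probabilities`` (optional, from the PSA) maps
    ``(horizon label, instrument)`` to ``{threshold: P(trab cost-effective)}``.
    Output rows are (horizon, instrument, arm) with incremental columns on
    the trabeculectomy row and the complement probabilities on the
    medication row.
    """
    from .states import ARM_MED, ARM_TRAB

    cells = sorted({(h, i) for (h, i, _a) in results}, key=str)
    rows = []
    for horizon, instrument in cells:
        try:
            trab = results[(horizon, instrument, ARM_TRAB)]
            med = results[(horizon, instrument, ARM_MED)]
        except KeyError as e:
            raise ValueError(f"both arms required for cell {(horizon, instrument)}") from e
        d_cost = trab.cost - med.cost
        d_qaly = trab.qalys - med.qalys
        ratio = icer(d_cost, d_qaly)
        probs = (ce_probabilities or {}).get((horizon, instrument), {})
        for arm, res, inc in ((ARM_TRAB, trab, True), (ARM_MED, med, False)):
            row = {
                "horizon": horizon,
                "instrument": instrument,
                "arm": arm,
                "Cost": res.cost,
                "dCost": d_cost if inc else np.nan,
                "QALY": res.qalys,
                "dQALY": d_qaly if inc else np.nan,
                "ICER": ratio if inc else np.nan,
                "NMB": nmb(res.cost, res.qalys, nmb_threshold),
            }
            for thr in thresholds:
                p = probs.get(thr)
                if p is None:
                    row[f"P(CE) at {thr:g}"] = np.nan
                else:
                    row[f"P(CE) at {thr:g}"] = p if inc else 1.0 - p
            rows.append(row)
    return pd.DataFrame(rows)
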