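"""Convenience layer: run both arms through the engine and economics.

These helpers are what the sensitivity-analysis module and the CLI call
repeatedly: one deterministic model evaluation for a ParamSet at a given
horizon and instrument, and the full multi-horizon multi-instrument
incremental table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .economics import (
    DEFAULT_THRESHOLDS,
    DiscountSpec,
    EconResult,
    accumulate,
    incremental_table,
)
from .markov import lifetime_horizon, run_cohort
from .params import INSTRUMENTS, ParamSet
from .states import ARM_MED, ARM_TRAB

LIFETIME = "lifetime"
DEFAULT_HORIZONS = (2, 10, LIFETIME)


def _horizon_cycles(param_set: ParamSet, horizon) -> int:
    return lifetime_horizon(param_set) if horizon == LIFETIME else int(horizon)


@dataclass(frozen=True)
class ArmOutcome:
    cost: float
    qalys: float


@dataclass(frozen=True)
class ModelOutcome:
    """Deterministic model evaluation for one horizon and instrument."""

    trabeculectomy: ArmOutcome
    medication: ArmOutcome

    @property
    def delta_cost(self) -> float:
        return self.trabeculectomy.cost - self.medication.cost

    @property
    def delta_qaly(self) -> float:
        return self.trabeculectomy.qalys - self.medication.qalys


def model_outcomes(
    param_set: ParamSet,
    horizon=LIFETIME,
    instrument: str = "eq5d",
    spec: DiscountSpec | None = None,
) -> ModelOutcome:
    """Run both arms and return per-arm discounted cost/QALYs."""
    cycles = _horizon_cycles(param_set, horizon)
    out = {}
    for arm in (ARM_TRAB, ARM_MED):
        trace = run_cohort(param_set, arm, horizon_years=cycles)
        res = accumulate(trace, param_set, instrument=instrument, spec=spec)
        out[arm] = ArmOutcome(cost=res.cost, qalys=res.qalys)
    return ModelOutcome(trabeculectomy=out[ARM_TRAB], medication=out[ARM_MED])


def evaluate(
    param_set: ParamSet,
    horizons=DEFAULT_HORIZONS,
    instruments=INSTRUMENTS,
    thresholds=DEFAULT_THRESHOLDS,
    spec: DiscountSpec | None = None,
    ce_probabilities: dict[tuple, dict[float, float]] | None = None,
) -> pd.DataFrame:
    """Full incremental table over horizons and utility instruments.

    Traces are run once per arm at the longest horizon and shorter horizons
    are accumulated from the same trace, so all horizon blocks are mutually
    consistent.
    """
    cycle_counts = {h: _horizon_cycles(param_set, h) for h in horizons}
    max_cycles = max(cycle_counts.values())
    traces = {
        arm: run_cohort(param_set, arm, horizon_years=max_cycles)
        for arm in (ARM_TRAB, ARM_MED)
    }
    results: dict[tuple, EconResult] = {}
    for h in horizons:
        for inst in instruments:
            for arm in (ARM_TRAB, ARM_MED):
                res = accumulate(
                    traces[arm],
                    param_set,
                    instrument=inst,
                    spec=spec,
                    horizon=cycle_counts[h],
                )
                results[(h, inst, arm)] = EconResult(
                    arm=arm, instrument=inst, horizon=h, cost=res.cost, qalys=res.qalys
                )
    return incremental_table(
        results, thresholds=thresholds, ce_probabilities=ce_probabilities
    )
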