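"""Probabilistic and deterministic sensitivity analysis.

The PSA propagates parameter uncertainty by Monte Carlo: costs follow gamma
and utilities beta distributions parameterised by method of moments; the
payoff regression coefficients are drawn jointly from a multinormal using
the Cholesky factor of their sampling covariance, which preserves the
correlation between severity and treatment effects; transition
probabilities estimated without a coefficient covariance fall back to
independent betas per transition.  Each iteration reruns the full Markov +
economics pipeline on the drawn parameter set.  Results feed the
cost-effectiveness acceptability curve (CEAC), the CE-plane confidence
ellipse, and — for the deterministic side — one-way tornado analyses and
time-horizon scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import DEFAULT_THRESHOLDS
from .estimation import payoffs_from_regressions
from .params import INSTRUMENTS, ParamSet, TransitionEstimate
from .pipeline import DEFAULT_HORIZONS, LIFETIME, evaluate, model_outcomes

CHI2_2DF_95 = 5.991464547107979  # chi-square 0.95 quantile, 2 df

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in range(0, 50_001, 500))


# ------------------------------------------------------------ distributions


def moments_to_gamma(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard error exactly."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if se <= 0:
        raise ValueError(f"gamma se must be > 0, got {se}")
    return mean**2 / se**2, se**2 / mean


def moments_to_beta(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean and standard error exactly."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError(f"beta se must be > 0, got {se}")
    if se**2 >= mean * (1.0 - mean):
        raise ValueError(f"se^2 = {se**2} not below mean(1-mean) = {mean * (1 - mean)}")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled parameter (or correlated block) in the PSA.

    ``param_id`` is a ParamSet address (see :func:`set_param`) for scalar
    families, or ``"regression/<outcome>"`` for a multinormal coefficient
    block whose draws are pushed through the payoff predictions.
    """

    param_id: str
    family: str  # 'gamma' | 'beta' | 'multinormal'
    mean: float | None = None
    se: float | None = None
    mean_vector: pd.Series | None = None
    covariance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.family == "gamma":
            if self.mean is None or self.mean <= 0 or self.se is None or self.se < 0:
                raise ValueError(f"invalid gamma spec for {self.param_id}")
        elif self.family == "beta":
            if self.mean is None or not 0.0 < self.mean < 1.0 or self.se is None:
                raise ValueError(f"invalid beta spec for {self.param_id}")
            if self.se > 0 and self.se**2 >= self.mean * (1.0 - self.mean):
                raise ValueError(f"beta se too large for {self.param_id}")
        elif self.family == "multinormal":
            if self.mean_vector is None or self.covariance is None:
                raise ValueError(f"multinormal spec {self.param_id} needs mean vector and covariance")
            cov = self.covariance.to_numpy()
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance for block {self.param_id} is not symmetric")
        else:
            raise ValueError(f"unknown family {self.family!r} for {self.param_id}")


def _cholesky_factor(block_id: str, cov: np.ndarray) -> np.ndarray:
    sym = 0.5 * (cov + cov.T)
    try:
        return np.linalg.cholesky(sym)
    except np.linalg.LinAlgError:
        eigvals, eigvecs = np.linalg.eigh(sym)
        tol = -1e-8 * max(1.0, float(eigvals.max(initial=0.0)))
        if eigvals.min() < tol:
            raise ValueError(
                f"covariance for block {block_id!r} is not positive semi-definite"
            ) from None
        return eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))


# ------------------------------------------------- ParamSet addressing


_SCALAR_FIELDS = (
    "discount_rate",
    "smr_unilateral",
    "smr_bilateral",
    "start_age",
    "female_fraction",
    "cost_scale",
)


def get_param(param_set: ParamSet, path: str) -> float:
    """Read a scalar ParamSet entry by address.

    Addresses: a bare field name (``discount_rate``, ``smr_unilateral``,
    ``smr_bilateral``, ``start_age``, ``female_fraction``, ``cost_scale``),
    ``utility_scale/<instrument>``, ``transition/<arm>/<from_level>``
    (annual probability) or ``payoff/<outcome>/<state>/<arm>``.
    """
    parts = path.split("/")
    head = parts[0]
    if head in _SCALAR_FIELDS:
        return float(getattr(param_set, head))
    if head == "utility_scale":
        return float(param_set.utility_scale[parts[1]])
    if head == "transition":
        return float(param_set.transitions[(parts[1], parts[2])].annual_probability)
    if head == "payoff":
        outcome, state, arm = parts[1], parts[2], parts[3]
        return float(param_set.payoffs.loc[(state, arm), outcome])
    raise KeyError(f"unknown parameter address {path!r}")


def set_param(param_set: ParamSet, path: str, value: float) -> ParamSet:
    """Return a copy of ``param_set`` with one scalar entry replaced."""
    parts = path.split("/")
    head = parts[0]
    if head in _SCALAR_FIELDS:
        value = int(round(value)) if head == "start_age" else float(value)
        return param_set.with_updates(**{head: value})
    if head == "utility_scale":
        scales = dict(param_set.utility_scale)
        if parts[1] not in scales:
            raise KeyError(f"unknown instrument {parts[1]!r}")
        scales[parts[1]] = float(value)
        return param_set.with_updates(utility_scale=scales)
    if head == "transition":
        arm, frm = parts[1], parts[2]
        old = param_set.transitions[(arm, frm)]
        transitions = dict(param_set.transitions)
        transitions[(arm, frm)] = TransitionEstimate(
            arm=arm,
            from_level=frm,
            to_level=old.to_level,
            annual_probability=float(np.clip(value, 0.0, 1.0)),
            standard_error=old.standard_error,
            events=old.events,
            eye_years=old.eye_years,
            wide_uncertainty=old.wide_uncertainty,
        )
        return param_set.with_updates(transitions=transitions)
    if head == "payoff":
        outcome, state, arm = parts[1], parts[2], parts[3]
        payoffs = param_set.payoffs.copy()
        if (state, arm) not in payoffs.index:
            raise KeyError(f"unknown payoff cell {(state, arm)}")
        payoffs.loc[(state, arm), outcome] = float(value)
        return param_set.with_updates(payoffs=payoffs)
    raise KeyError(f"unknown parameter address {path!r}")


def list_parameters(param_set: ParamSet) -> dict[str, float]:
    """All addressable scalar parameters with their current values."""
    out = {f: float(getattr(param_set, f)) for f in _SCALAR_FIELDS}
    for inst in param_set.utility_scale:
        out[f"utility_scale/{inst}"] = float(param_set.utility_scale[inst])
    for (arm, frm), est in param_set.transitions.items():
        out[f"transition/{arm}/{frm}"] = est.annual_probability
    for (state, arm), row in param_set.payoffs.iterrows():
        for outcome, value in row.items():
            out[f"payoff/{outcome}/{state}/{arm}"] = float(value)
    return out


# -------------------------------------------------------------- sampling


def default_psa_specs(param_set: ParamSet) -> list[DistributionSpec]:
    """Default uncertainty model for an estimated ParamSet.

    Payoff regression coefficients (cost and the three utilities) enter as
    multinormal blocks with their OLS covariance; transition probabilities
    enter as independent betas from their (probability, SE) pairs.
    Zero-event transitions and ParamSets without attached regressions
    contribute no sampled parameters and stay at their base values.
    """
    specs: list[DistributionSpec] = []
    for (arm, frm), est in sorted(param_set.transitions.items()):
        p, se = est.annual_probability, est.standard_error
        if se > 0 and 0.0 < p < 1.0 and se**2 < p * (1.0 - p):
            specs.append(
                DistributionSpec(
                    param_id=f"transition/{arm}/{frm}", family="beta", mean=p, se=se
                )
            )
    if param_set.regressions:
        for outcome in sorted(param_set.regressions):
            reg = param_set.regressions[outcome]
            specs.append(
                DistributionSpec(
                    param_id=f"regression/{outcome}",
                    family="multinormal",
                    mean_vector=reg.coefficients,
                    covariance=reg.covariance,
                )
            )
    return specs


def sample_param_set(
    specs: list[DistributionSpec], base: ParamSet, rng: np.random.Generator
) -> ParamSet:
    """One Monte-Carlo draw of a ParamSet.

    Scalar families draw independently; multinormal blocks draw jointly via
    the Cholesky factor and are pushed through the payoff predictions.  All
    draws respect the model's constraints (probabilities in [0, 1],
    utilities clamped to <= 1, costs >= 0).  With all SEs zero the draw
    equals the base ParamSet.
    """
    ps = base
    coef_overrides: dict[str, pd.Series] = {}
    for spec in specs:
        if spec.family == "gamma":
            if spec.se == 0:
                value = spec.mean
            else:
                shape, scale = moments_to_gamma(spec.mean, spec.se)
                value = float(rng.gamma(shape, scale))
            ps = set_param(ps, spec.param_id, max(value, 0.0))
        elif spec.family == "beta":
            if spec.se == 0:
                value = spec.mean
            else:
                a, b = moments_to_beta(spec.mean, spec.se)
                value = float(rng.beta(a, b))
            ps = set_param(ps, spec.param_id, float(np.clip(value, 0.0, 1.0)))
        else:
            mean = spec.mean_vector.to_numpy(dtype=float)
            L = _cholesky_factor(spec.param_id, spec.covariance.to_numpy(dtype=float))
            draw = mean + L @ rng.standard_normal(len(mean))
            outcome = spec.param_id.split("/", 1)[1]
            coef_overrides[outcome] = pd.Series(draw, index=spec.mean_vector.index)
    if coef_overrides:
        if not base.regressions:
            raise ValueError("multinormal regression block given but ParamSet has no regressions")
        full = {
            o: coef_overrides.get(o, base.regressions[o].coefficients)
            for o in base.regressions
        }
        payoffs = payoffs_from_regressions(base.regressions, base.scale, full)
        ps = ps.with_updates(payoffs=payoffs)
    return ps


SAMPLE_COLUMNS = [
    "iteration",
    "cost_trabeculectomy",
    "qaly_trabeculectomy",
    "cost_medication",
    "qaly_medication",
    "delta_cost",
    "delta_qaly",
]


def run_psa_cells(
    param_set: ParamSet,
    n_iterations: int = 10_000,
    seed: int = 0,
    horizons=(LIFETIME,),
    instruments=("eq5d",),
    specs: list[DistributionSpec] | None = None,
) -> dict[tuple, pd.DataFrame]:
    """Monte-Carlo PSA over every (horizon, instrument) cell at once.

    Each iteration draws one ParamSet, runs one trace per arm at the
    longest horizon, and accumulates every cell from those traces — so all
    cells share the same parameter draws.  Deterministic given ``seed``;
    iteration ``i`` uses the ``i``-th spawned child stream, so individual
    iterations are independently reproducible.
    """
    from .economics import DiscountSpec, accumulate
    from .markov import lifetime_horizon, run_cohort
    from .states import ARM_MED, ARM_TRAB

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if specs is None:
        specs = default_psa_specs(param_set)
    cycle_counts = {
        h: (lifetime_horizon(param_set) if h == LIFETIME else int(h)) for h in horizons
    }
    max_cycles = max(cycle_counts.values())
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    rows: dict[tuple, list] = {(h, i): [] for h in horizons for i in instruments}
    for i in range(n_iterations):
        rng = np.random.default_rng(children[i])
        draw = sample_param_set(specs, param_set, rng)
        spec = DiscountSpec(draw.discount_rate)
        traces = {
            arm: run_cohort(draw, arm, horizon_years=max_cycles)
            for arm in (ARM_TRAB, ARM_MED)
        }
        for h in horizons:
            for inst in instruments:
                res = {
                    arm: accumulate(
                        traces[arm], draw, instrument=inst, spec=spec,
                        horizon=cycle_counts[h],
                    )
                    for arm in (ARM_TRAB, ARM_MED)
                }
                rows[(h, inst)].append(
                    (
                        i,
                        res[ARM_TRAB].cost,
                        res[ARM_TRAB].qalys,
                        res[ARM_MED].cost,
                        res[ARM_MED].qalys,
                        res[ARM_TRAB].cost - res[ARM_MED].cost,
                        res[ARM_TRAB].qalys - res[ARM_MED].qalys,
                    )
                )
    return {
        cell: pd.DataFrame(data, columns=SAMPLE_COLUMNS) for cell, data in rows.items()
    }


def run_psa(
    param_set: ParamSet,
    n_iterations: int = 10_000,
    seed: int = 0,
    horizon=LIFETIME,
    instrument: str = "eq5d",
    specs: list[DistributionSpec] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo PSA for a single (horizon, instrument) cell."""
    cells = run_psa_cells(
        param_set,
        n_iterations=n_iterations,
        seed=seed,
        horizons=(horizon,),
        instruments=(instrument,),
        specs=specs,
    )
    return cells[(horizon, instrument)]


# ------------------------------------------------------------------ CEAC


def ceac(samples: pd.DataFrame, thresholds=DEFAULT_LAMBDA_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each threshold, trabeculectomy counts as cost-effective when its
    incremental net monetary benefit is strictly positive (ties go to the
    incumbent, medication); the two arms' probabilities sum to 1.
    """
    if len(samples) == 0:
        raise ValueError("ceac needs at least one PSA sample")
    dc = samples["delta_cost"].to_numpy()
    dq = samples["delta_qaly"].to_numpy()
    rows = []
    for lam in thresholds:
        p = float(np.mean(lam * dq - dc > 0.0))
        rows.append((float(lam), p, 1.0 - p))
    return pd.DataFrame(
        rows, columns=["threshold", "p_trabeculectomy", "p_medication"]
    )


def ceac_probabilities(
    samples_by_cell: dict[tuple, pd.DataFrame], thresholds=DEFAULT_THRESHOLDS
) -> dict[tuple, dict[float, float]]:
    """P(trabeculectomy cost-effective) per (horizon, instrument) cell."""
    out = {}
    for cell, samples in samples_by_cell.items():
        curve = ceac(samples, thresholds)
        out[cell] = dict(zip(curve["threshold"], curve["p_trabeculectomy"]))
    return out


# -------------------------------------------------------------- CE plane


@dataclass(frozen=True)
class CePlane:
    """Bivariate-normal summary of the (ΔQALY, ΔCost) cloud.

    The 95% confidence ellipse uses the chi-square 2-df radius; axes are
    reported as (half-length, direction angle) pairs.  ``degenerate`` flags
    clouds whose covariance has rank < 2 (point or segment), for which the
    ellipse is not defined.
    """

    mean_dqaly: float
    mean_dcost: float
    covariance: np.ndarray
    degenerate: bool
    axis_lengths: tuple[float, float] | None
    angle: float | None

    def mahalanobis_sq(self, dqaly, dcost) -> np.ndarray:
        if self.degenerate:
            raise ValueError("degenerate CE plane has no ellipse")
        delta = np.stack(
            [np.asarray(dqaly) - self.mean_dqaly, np.asarray(dcost) - self.mean_dcost]
        )
        return np.einsum("ij,ij->j", delta, np.linalg.solve(self.covariance, delta))

    def contains(self, dqaly, dcost) -> np.ndarray:
        """Whether points fall inside the 95% ellipse."""
        return self.mahalanobis_sq(dqaly, dcost) <= CHI2_2DF_95


def ce_plane(samples: pd.DataFrame) -> CePlane:
    """Fit the CE-plane confidence ellipse from PSA samples."""
    if len(samples) < 3:
        raise ValueError("ce_plane needs at least 3 samples")
    pts = samples[["delta_qaly", "delta_cost"]].to_numpy(dtype=float)
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    scale = max(float(eigvals.max(initial=0.0)), 0.0)
    degenerate = bool(scale <= 0.0 or eigvals.min() <= 1e-12 * scale)
    if degenerate:
        lengths, angle = None, None
    else:
        lengths = tuple(float(math.sqrt(v * CHI2_2DF_95)) for v in eigvals[::-1])
        major = eigvecs[:, -1]
        angle = float(math.atan2(major[1], major[0]))
    return CePlane(
        mean_dqaly=float(mean[0]),
        mean_dcost=float(mean[1]),
        covariance=cov,
        degenerate=degenerate,
        axis_lengths=lengths,
        angle=angle,
    )


# ---------------------------------------------------------- deterministic


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    param_id: str
    low: float
    high: float
    result_low: float
    result_high: float

    @property
    def width(self) -> float:
        return abs(self.result_high - self.result_low)


def _incremental_result(
    param_set: ParamSet, outcome: str, wtp: float, horizon, instrument: str
):
    out = model_outcomes(param_set, horizon=horizon, instrument=instrument)
    if outcome == "nmb":
        return wtp * out.delta_qaly - out.delta_cost
    if outcome == "icer":
        from .economics import icer

        return icer(out.delta_cost, out.delta_qaly)
    raise ValueError(f"unknown outcome {outcome!r}")


def one_way(
    param_set: ParamSet,
    param_id: str,
    low: float,
    high: float,
    wtp: float = 20_000.0,
    horizon=LIFETIME,
    instrument: str = "eq5d",
    outcome: str = "nmb",
) -> TornadoEntry:
    """Deterministic model runs at the two bounds of one parameter.

    All other parameters stay at base case; the default outcome is the
    incremental net monetary benefit at £20 000 per QALY.
    """
    if low > high:
        raise ValueError(f"low {low} exceeds high {high} for {param_id}")
    res = []
    for bound in (low, high):
        ps = set_param(param_set, param_id, bound)
        res.append(_incremental_result(ps, outcome, wtp, horizon, instrument))
    return TornadoEntry(
        param_id=param_id, low=low, high=high, result_low=res[0], result_high=res[1]
    )


def default_tornado_ranges(
    param_set: ParamSet, instrument: str = "eq5d", relative: float = 0.2
) -> dict[str, tuple[float, float]]:
    """Conventional one-way ranges: ±20% of base value where meaningful.

    Discount rate runs 0–7%, SMRs from 1 upward, and probabilities are
    clipped to [0, 1]."""
    ranges: dict[str, tuple[float, float]] = {
        "discount_rate": (0.0, 0.07),
        "smr_unilateral": (1.0, param_set.smr_unilateral * (1 + relative) + 0.5),
        "smr_bilateral": (1.0, param_set.smr_bilateral * (1 + relative) + 0.5),
        "cost_scale": (1.0 - relative, 1.0 + relative),
        f"utility_scale/{instrument}": (1.0 - relative / 2, 1.0 + relative / 2),
    }
    for (arm, frm), est in sorted(param_set.transitions.items()):
        p = est.annual_probability
        ranges[f"transition/{arm}/{frm}"] = (
            max(0.0, p * (1 - relative)),
            min(1.0, p * (1 + relative)),
        )
    return ranges


def tornado(
    param_set: ParamSet,
    ranges: dict[str, tuple[float, float]] | None = None,
    wtp: float = 20_000.0,
    horizon=LIFETIME,
    instrument: str = "eq5d",
) -> pd.DataFrame:
    """One-way analyses for a set of parameters, sorted by bar width."""
    if ranges is None:
        ranges = default_tornado_ranges(param_set, instrument)
    entries = [
        one_way(param_set, pid, lo, hi, wtp=wtp, horizon=horizon, instrument=instrument)
        for pid, (lo, hi) in ranges.items()
    ]
    df = pd.DataFrame(
        {
            "param_id": [e.param_id for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "result_low": [e.result_low for e in entries],
            "result_high": [e.result_high for e in entries],
            "width": [e.width for e in entries],
        }
    )
    return df.sort_values("width", ascending=False, kind="stable").reset_index(drop=True)


def scenario_horizons(
    param_set: ParamSet,
    horizons=DEFAULT_HORIZONS,
    instruments=INSTRUMENTS,
    thresholds=DEFAULT_THRESHOLDS,
) -> dict[object, pd.DataFrame]:
    """Full incremental tables at each time horizon (2y, 10y, lifetime)."""
    return {
        h: evaluate(param_set, horizons=(h,), instruments=instruments, thresholds=thresholds)
        for h in horizons
    }
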