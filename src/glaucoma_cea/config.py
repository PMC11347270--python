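"""Structured run configuration: defaults, YAML loading, seed splitting.

One YAML file drives the whole pipeline.  Top-level keys: ``seed`` (root
seed; each stage derives its own child deterministically), ``trial``
(overrides for :class:`~glaucoma_cea.synthetic.TrialConfig` fields),
``model`` (SMRs, discount rate, cohort profile, estimator choice),
``psa`` (iteration count), plus ``horizons``, ``instruments`` and
``thresholds`` for reporting.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from .lifetable import LifeTable, make_gompertz_life_table
from .synthetic import TrialConfig

DEFAULT_CONFIG: dict = {
    "seed": 20240,
    "trial": {},  # TrialConfig field overrides (see synthetic.TrialConfig)
    "model": {
        "discount_rate": 0.035,
        "smr_unilateral": 1.0,
        "smr_bilateral": 1.0,
        "start_age": 67,
        "female_fraction": 0.3,
        "transition_method": "exponential",  # or "logistic"
    },
    "psa": {"n_iterations": 2000},
    "horizons": [2, 10, "lifetime"],
    "instruments": ["eq5d", "hui3", "gui"],
    "thresholds": [0.0, 10_000.0, 20_000.0, 50_000.0],
    "life_table": None,  # path to CSV; None -> synthetic Gompertz table
}

_STAGES = ("simulate", "estimate", "run", "psa", "dsa", "report")


def load_config(path=None) -> dict:
    """Packaged defaults, shallow-merged per section with a YAML file."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(Path(path)) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the root seed."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([int(root_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def life_table_from_config(cfg: dict) -> LifeTable:
    path = cfg.get("life_table")
    return LifeTable.read(path) if path else make_gompertz_life_table()


def trial_config_from_config(cfg: dict) -> TrialConfig:
    """TrialConfig with the config's overrides and the stage-derived seed."""
    overrides = dict(cfg.get("trial", {}))
    if "hazards" in overrides:
        overrides["hazards"] = {a: dict(h) for a, h in overrides["hazards"].items()}
    for key in ("cost_mean",):
        if key in overrides:
            overrides[key] = {a: tuple(v) for a, v in overrides[key].items()}
    for key in ("utility_mean",):
        if key in overrides:
            overrides[key] = {i: tuple(v) for i, v in overrides[key].items()}
    for key in ("index_state_probs", "fellow_state_probs"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    overrides.setdefault("rng_seed", stage_seed(cfg["seed"], "simulate"))
    overrides.setdefault("life_table", life_table_from_config(cfg))
    model = cfg.get("model", {})
    overrides.setdefault("smr_unilateral", model.get("smr_unilateral", 1.0))
    overrides.setdefault("smr_bilateral", model.get("smr_bilateral", 1.0))
    return TrialConfig(**overrides)
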