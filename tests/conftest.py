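import numpy as np
import pytest

import glaucoma_cea as g


@pytest.fixture(scope="session")
def small_config() -> g.TrialConfig:
    """Small but fully featured trial: fast to generate, all levels reachable."""
    return g.TrialConfig(n_participants=300, followup_years=4, rng_seed=11)


@pytest.fixture(scope="session")
def small_records(small_config):
    return g.generate_trial(small_config)


@pytest.fixture(scope="session")
def default_config() -> g.TrialConfig:
    return g.TrialConfig()


@pytest.fixture(scope="session")
def truth_params(default_config) -> g.ParamSet:
    """ParamSet built from generator truth (no estimation noise)."""
    return g.truth_param_set(default_config)


@pytest.fixture(scope="session")
def estimated_params(default_config) -> g.ParamSet:
    records = g.generate_trial(default_config)
    return g.estimate_params(
        records,
        default_config.life_table,
        start_age=int(round(default_config.baseline_age_mean)),
        female_fraction=default_config.prop_female,
    )


def microsimulate(param_set, arm, horizon, n_individuals, seed):
    """Individual-level Monte-Carlo oracle for the cohort trace.

    Samples each individual's path through the same annual transition
    matrices the engine builds, and returns empirical state occupancies per
    cycle.  Independent of the engine's matrix-multiplication path.
    """
    rng = np.random.default_rng(seed)
    space = param_set.space
    n_states = space.n_states
    init = (
        param_set.initial_distribution.reindex(space.live_states).fillna(0.0).to_numpy()
    )
    state = rng.choice(space.n_live, size=n_individuals, p=init / init.sum())
    occ = np.zeros((horizon + 1, n_states))
    occ[0] = np.bincount(state, minlength=n_states) / n_individuals
    for t in range(horizon):
        mat = g.build_transition_matrix(
            param_set, arm, param_set.start_age + t, "mixed"
        ).to_numpy()
        u = rng.random(n_individuals)
        cum = np.cumsum(mat[state], axis=1)
        state = (u[:, None] > cum).sum(axis=1)
        occ[t + 1] = np.bincount(state, minlength=n_states) / n_individuals
    return occ
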