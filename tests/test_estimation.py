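"""Estimation: rate/probability conversions, time-to-event transition
estimates, payoff regressions and ParamSet assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glaucoma_cea as g
from glaucoma_cea.params import OUTCOMES, TransitionEstimate
from glaucoma_cea.states import ARM_MED, ARM_TRAB


class TestRateProbConversion:
    def test_closed_forms(self):
        assert g.rate_to_prob(0.0, 1.0) == 0.0
        assert g.rate_to_prob(np.log(2.0), 1.0) == pytest.approx(0.5)
        assert g.rate_to_prob(0.2, 1.0) == pytest.approx(0.18127, abs=1e-5)
        assert g.prob_to_rate(0.0) == 0.0
        assert g.prob_to_rate(0.5) == pytest.approx(np.log(2.0))

    @given(st.floats(min_value=0.0, max_value=0.999), st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None)
    def test_exact_inverses(self, p, t):
        assert g.rate_to_prob(g.prob_to_rate(p, t), t) == pytest.approx(p, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            g.rate_to_prob(-0.1)
        with pytest.raises(ValueError):
            g.prob_to_rate(1.0)
        with pytest.raises(ValueError):
            g.rate_to_prob(0.1, t=0.0)


class TestTransitionEstimates:
    def test_counts_closed_form(self):
        est = TransitionEstimate.from_counts(ARM_MED, "advanced", "severe", 50, 250.0)
        assert est.underlying_rate == pytest.approx(0.2)
        assert est.annual_probability == pytest.approx(0.18127, abs=1e-5)
        # invariant: p = 1 - exp(-rate) to numerical precision
        assert est.annual_probability == pytest.approx(
            g.rate_to_prob(est.underlying_rate), abs=1e-12
        )

    def test_zero_events_flagged_wide(self):
        est = TransitionEstimate.from_counts(ARM_TRAB, "severe", "end_stage", 0, 100.0)
        assert est.annual_probability == 0.0
        assert est.wide_uncertainty

    def test_zero_exposure_errors_with_transition_named(self):
        with pytest.raises(ValueError, match="severe->end_stage"):
            TransitionEstimate.from_counts(ARM_TRAB, "severe", "end_stage", 0, 0.0)

    def test_no_progression_anywhere_gives_zero_probabilities(self):
        hazards = {
            a: {l: 0.0 for l in ("advanced", "severe", "end_stage")}
            for a in (ARM_TRAB, ARM_MED)
        }
        cfg = g.TrialConfig(
            n_participants=300,
            followup_years=3,
            hazards=hazards,
            fellow_state_probs=(0.4, 0.3, 0.2, 0.1),
            rng_seed=13,
        )
        records = g.generate_trial(cfg)
        est = g.estimate_transitions(records)
        assert all(t.annual_probability == 0.0 for t in est.values())
        assert all(t.wide_uncertainty for t in est.values())

    def test_hazard_recovery_at_large_exposure(self):
        """Parameter recovery: hazard 0.15 recovered within 3 SE from
        >= 20 000 eye-years of annual-inspection data."""
        hazards = {
            a: {"advanced": 0.15, "severe": 0.15, "end_stage": 0.15}
            for a in (ARM_TRAB, ARM_MED)
        }
        cfg = g.TrialConfig(
            n_participants=3000,
            followup_years=5,
            hazards=hazards,
            rng_seed=29,
        )
        records = g.generate_trial(cfg)
        est = g.estimate_transitions(records)
        e = est[(ARM_MED, "advanced")]
        assert e.eye_years > 5000
        se_rate = np.sqrt(e.events) / e.eye_years
        assert abs(e.underlying_rate - 0.15) < 3 * se_rate

    def test_logistic_estimator_agrees_on_probability_scale(self, small_records):
        expo = g.estimate_transitions(small_records, method="exponential")
        logi = g.estimate_transitions(small_records, method="logistic")
        for key in expo:
            # same events/intervals; estimators differ only via exposure convention
            assert logi[key].annual_probability == pytest.approx(
                expo[key].annual_probability, abs=0.02
            )


class TestPayoffRegression:
    def _noise_free_records(self, n=400, cost_by_level=(500.0, 800.0, 1100.0, 1400.0)):
        cfg = g.TrialConfig(
            n_participants=n,
            followup_years=3,
            cost_mean={ARM_TRAB: cost_by_level, ARM_MED: cost_by_level},
            cost_se_fraction=0.0,
            utility_se=0.0,
            fellow_state_probs=(0.4, 0.3, 0.2, 0.1),
            rng_seed=31,
        )
        return g.generate_trial(cfg)

    def test_noise_free_cost_recovered_exactly(self):
        records = self._noise_free_records()
        reg = g.fit_payoff_regression(records, "annual_cost")
        assert reg.coefficients["intercept"] == pytest.approx(500.0, abs=1e-8)
        assert reg.coefficients["level[severe]"] == pytest.approx(300.0, abs=1e-8)
        assert reg.coefficients["level[end_stage]"] == pytest.approx(600.0, abs=1e-8)
        assert reg.coefficients["level[blind]"] == pytest.approx(900.0, abs=1e-8)
        assert reg.coefficients["treatment"] == pytest.approx(0.0, abs=1e-8)

    def test_identical_outcomes_give_zero_slopes(self):
        records = self._noise_free_records(cost_by_level=(750.0,) * 4)
        reg = g.fit_payoff_regression(records, "annual_cost")
        for term in ("level[severe]", "level[end_stage]", "level[blind]", "treatment"):
            assert reg.coefficients[term] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(reg.covariance.to_numpy(), 0.0, atol=1e-8)

    def test_utility_severity_effects_monotone_decreasing(self):
        cfg = g.TrialConfig(
            n_participants=5000,
            followup_years=2,
            fellow_state_probs=(0.4, 0.3, 0.2, 0.1),
            index_state_probs=(0.6, 0.25, 0.1, 0.05),
            rng_seed=37,
        )
        records = g.generate_trial(cfg)
        reg = g.fit_payoff_regression(records, "utility_eq5d")
        effects = [
            0.0,
            reg.coefficients["level[severe]"],
            reg.coefficients["level[end_stage]"],
            reg.coefficients["level[blind]"],
        ]
        assert all(b < a for a, b in zip(effects, effects[1:]))

    def test_rank_deficient_design_names_empty_columns(self):
        cfg = g.TrialConfig(
            n_participants=100,
            followup_years=1,
            hazards={a: {l: 0.0 for l in ("advanced", "severe", "end_stage")} for a in (ARM_TRAB, ARM_MED)},
            index_state_probs=(1.0, 0, 0, 0),
            fellow_state_probs=(1.0, 0, 0, 0),
            rng_seed=41,
        )
        records = g.generate_trial(cfg)
        with pytest.raises(ValueError, match="level"):
            g.fit_payoff_regression(records, "annual_cost")


class TestBuildParamSet:
    def test_assembled_set_passes_invariants(self, estimated_params):
        ps = estimated_params
        for arm in (ARM_TRAB, ARM_MED):
            for frm, _to in ps.scale.adjacent_pairs():
                assert 0.0 <= ps.transitions[(arm, frm)].annual_probability <= 1.0
        assert (ps.payoffs["annual_cost"] >= 0).all()
        for col in ("utility_eq5d", "utility_hui3", "utility_gui"):
            assert (ps.payoffs[col] <= 1.0).all()
        assert ps.initial_distribution.sum() == pytest.approx(1.0)

    def test_utility_predictions_clamped_to_one(self, small_records):
        regs = {o: g.fit_payoff_regression(small_records, o) for o in OUTCOMES}
        coef = regs["utility_eq5d"].coefficients.copy()
        coef["intercept"] = 1.4  # force out-of-range predictions
        from glaucoma_cea.estimation import payoffs_from_regressions

        payoffs = payoffs_from_regressions(
            regs, g.SeverityScale(), {"utility_eq5d": coef}
        )
        assert payoffs["utility_eq5d"].max() == 1.0

    def test_missing_transition_rejected(self, estimated_params):
        broken = dict(estimated_params.transitions)
        del broken[(ARM_MED, "severe")]
        with pytest.raises(ValueError, match="severe"):
            estimated_params.with_updates(transitions=broken)

    def test_round_trip_through_bundle_directory(self, estimated_params, tmp_path):
        estimated_params.save(tmp_path / "bundle")
        again = g.ParamSet.load(tmp_path / "bundle")
        assert again.scale == estimated_params.scale
        for key, est in estimated_params.transitions.items():
            assert again.transitions[key].annual_probability == pytest.approx(
                est.annual_probability, abs=1e-12
            )
        pd.testing.assert_frame_equal(again.payoffs, estimated_params.payoffs)
        pd.testing.assert_series_equal(
            again.initial_distribution, estimated_params.initial_distribution
        )
        assert again.discount_rate == estimated_params.discount_rate
        for o, reg in estimated_params.regressions.items():
            pd.testing.assert_series_equal(
                again.regressions[o].coefficients, reg.coefficients, check_names=False
            )


def test_parameter_recovery_coverage_over_replications():
    """Estimated hazards, cost and utility means fall inside their 95%
    intervals of generator truth in >= 90% of seeded replications."""
    n_rep = 50
    hits = {"hazard": [], "cost": [], "utility": []}
    truth_hazard = g.TrialConfig().hazards[ARM_MED]["advanced"]
    truth_cost = g.TrialConfig().cost_mean[ARM_MED][0]
    truth_util = g.TrialConfig().utility_mean["eq5d"][0]
    for rep in range(n_rep):
        cfg = g.TrialConfig(n_participants=2000, followup_years=5, rng_seed=1000 + rep)
        records = g.generate_trial(cfg)
        est = g.estimate_transitions(records)[(ARM_MED, "advanced")]
        se_rate = np.sqrt(est.events) / est.eye_years
        hits["hazard"].append(abs(est.underlying_rate - truth_hazard) < 1.96 * se_rate)

        reg_c = g.fit_payoff_regression(records, "annual_cost")
        se_c = np.sqrt(reg_c.covariance.loc["intercept", "intercept"])
        hits["cost"].append(abs(reg_c.predict("advanced", ARM_MED) - truth_cost) < 1.96 * se_c)

        reg_u = g.fit_payoff_regression(records, "utility_eq5d")
        se_u = np.sqrt(reg_u.covariance.loc["intercept", "intercept"])
        hits["utility"].append(
            abs(reg_u.predict("advanced", ARM_MED) - truth_util) < 1.96 * se_u
        )
    for quantity, ok in hits.items():
        assert np.mean(ok) >= 0.9, f"{quantity} coverage {np.mean(ok):.2f}"
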