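"""PSA machinery: moment-matched distributions, correlated draws, CEAC,
CE-plane ellipse, tornado and horizon scenarios."""

import numpy as np
import pandas as pd
import pytest

import glaucoma_cea as g
from glaucoma_cea.uncertainty import (
    DEFAULT_LAMBDA_GRID,
    default_psa_specs,
    default_tornado_ranges,
    get_param,
    list_parameters,
    set_param,
)


class TestMomentConversions:
    def test_gamma_closed_form(self):
        assert g.moments_to_gamma(100.0, 10.0) == pytest.approx((100.0, 1.0))

    def test_gamma_exponential_boundary(self):
        shape, scale = g.moments_to_gamma(37.0, 37.0)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(37.0)

    def test_beta_closed_form(self):
        a, b = g.moments_to_beta(0.8, 0.1)
        assert a == pytest.approx(12.0)
        assert b == pytest.approx(3.0)

    def test_beta_symmetry_at_half(self):
        a, b = g.moments_to_beta(0.5, 0.05)
        assert a == pytest.approx(b)

    def test_infeasible_beta_rejected(self):
        with pytest.raises(ValueError):
            g.moments_to_beta(0.5, 0.5)

    @pytest.mark.parametrize("mean,se", [(100.0, 10.0), (5.0, 2.0)])
    def test_gamma_moments_reproduced(self, mean, se):
        shape, scale = g.moments_to_gamma(mean, se)
        assert shape * scale == pytest.approx(mean)
        assert np.sqrt(shape) * scale == pytest.approx(se)


class TestParamAddressing:
    def test_round_trip_scalars(self, truth_params):
        for path in ("discount_rate", "smr_bilateral", "cost_scale"):
            value = get_param(truth_params, path)
            bumped = set_param(truth_params, path, value + 0.5)
            assert get_param(bumped, path) == pytest.approx(value + 0.5)

    def test_transition_and_payoff_addresses(self, truth_params):
        p0 = get_param(truth_params, "transition/medication/advanced")
        ps = set_param(truth_params, "transition/medication/advanced", 0.2)
        assert get_param(ps, "transition/medication/advanced") == 0.2
        assert p0 != 0.2
        c0 = get_param(
            truth_params, "payoff/annual_cost/advanced:severe/trabeculectomy"
        )
        ps2 = set_param(
            truth_params, "payoff/annual_cost/advanced:severe/trabeculectomy", c0 + 1
        )
        assert get_param(
            ps2, "payoff/annual_cost/advanced:severe/trabeculectomy"
        ) == pytest.approx(c0 + 1)

    def test_unknown_address_rejected(self, truth_params):
        with pytest.raises(KeyError):
            get_param(truth_params, "nonsense/path")

    def test_listing_covers_transitions_and_scalars(self, truth_params):
        params = list_parameters(truth_params)
        assert "discount_rate" in params
        assert "transition/trabeculectomy/end_stage" in params
        assert any(p.startswith("payoff/annual_cost/") for p in params)


class TestSampling:
    def test_zero_variance_specs_reproduce_base(self, truth_params):
        specs = [
            g.DistributionSpec("payoff/annual_cost/advanced:advanced/medication", "gamma", mean=600.0, se=0.0),
            g.DistributionSpec("transition/medication/advanced", "beta", mean=0.3, se=0.0),
        ]
        rng = np.random.default_rng(0)
        draw = g.sample_param_set(specs, truth_params, rng)
        assert get_param(draw, "payoff/annual_cost/advanced:advanced/medication") == 600.0
        assert get_param(draw, "transition/medication/advanced") == 0.3

    def test_gamma_sample_mean_matches_spec(self, truth_params):
        specs = [
            g.DistributionSpec(
                "payoff/annual_cost/advanced:advanced/medication", "gamma", mean=100.0, se=10.0
            )
        ]
        rng = np.random.default_rng(123)
        n = 10_000
        draws = np.array(
            [
                get_param(
                    g.sample_param_set(specs, truth_params, rng),
                    "payoff/annual_cost/advanced:advanced/medication",
                )
                for _ in range(n)
            ]
        )
        assert abs(draws.mean() - 100.0) < 3 * 10.0 / np.sqrt(n)

    def test_multinormal_block_preserves_correlation(self):
        """rho = 0.9 in the coefficient covariance appears in the draws."""
        mean = pd.Series({"intercept": 0.0, "treatment": 0.0})
        rho = 0.9
        cov = pd.DataFrame(
            [[1.0, rho], [rho, 1.0]], index=mean.index, columns=mean.index
        )
        from glaucoma_cea.uncertainty import _cholesky_factor

        L = _cholesky_factor("test", cov.to_numpy())
        rng = np.random.default_rng(7)
        z = rng.standard_normal((10_000, 2))
        draws = z @ L.T
        r = np.corrcoef(draws.T)[0, 1]
        assert abs(r - rho) < 0.03

    def test_non_psd_covariance_rejected_with_block_named(self):
        mean = pd.Series({"a": 0.0, "b": 0.0})
        cov = pd.DataFrame(
            [[1.0, 2.0], [2.0, 1.0]], index=mean.index, columns=mean.index
        )
        spec = g.DistributionSpec(
            "regression/annual_cost", "multinormal", mean_vector=mean, covariance=cov
        )
        from glaucoma_cea.uncertainty import _cholesky_factor

        with pytest.raises(ValueError, match="regression/annual_cost"):
            _cholesky_factor(spec.param_id, cov.to_numpy())

    def test_regression_block_draws_propagate_to_payoffs(self, estimated_params):
        specs = default_psa_specs(estimated_params)
        assert any(s.family == "multinormal" for s in specs)
        assert any(s.family == "beta" for s in specs)
        rng = np.random.default_rng(11)
        draw = g.sample_param_set(specs, estimated_params, rng)
        assert not np.allclose(
            draw.payoffs["annual_cost"], estimated_params.payoffs["annual_cost"]
        )
        for col in ("utility_eq5d", "utility_hui3", "utility_gui"):
            assert (draw.payoffs[col] <= 1.0).all()
        assert (draw.payoffs["annual_cost"] >= 0.0).all()


class TestRunPsa:
    def test_zero_variance_collapses_to_base_case(self, truth_params):
        base = g.model_outcomes(truth_params, horizon=10)
        samples = g.run_psa(truth_params, n_iterations=5, seed=3, horizon=10, specs=[])
        assert np.allclose(samples["delta_cost"], base.delta_cost)
        assert np.allclose(samples["delta_qaly"], base.delta_qaly)
        assert samples["delta_cost"].nunique() == 1

    def test_bit_reproducible_under_fixed_seed(self, estimated_params):
        a = g.run_psa(estimated_params, n_iterations=8, seed=42, horizon=10)
        b = g.run_psa(estimated_params, n_iterations=8, seed=42, horizon=10)
        pd.testing.assert_frame_equal(a, b)
        c = g.run_psa(estimated_params, n_iterations=8, seed=43, horizon=10)
        assert not np.allclose(a["delta_cost"], c["delta_cost"])

    def test_psa_mean_consistent_with_base_case(self, estimated_params):
        samples = g.run_psa(estimated_params, n_iterations=200, seed=5, horizon=10)
        base = g.model_outcomes(estimated_params, horizon=10)
        se = samples["delta_cost"].std() / np.sqrt(len(samples))
        assert abs(samples["delta_cost"].mean() - base.delta_cost) < 4 * se

    def test_cells_share_draws(self, estimated_params):
        cells = g.run_psa_cells(
            estimated_params,
            n_iterations=5,
            seed=9,
            horizons=(2, 10),
            instruments=("eq5d", "gui"),
        )
        assert set(cells) == {(2, "eq5d"), (2, "gui"), (10, "eq5d"), (10, "gui")}
        # same draws: per-iteration costs at a horizon agree across instruments
        assert np.allclose(
            cells[(2, "eq5d")]["delta_cost"], cells[(2, "gui")]["delta_cost"]
        )


class TestCeac:
    def _samples(self, rows):
        df = pd.DataFrame(rows, columns=["delta_cost", "delta_qaly"])
        df["iteration"] = range(len(df))
        return df

    def test_hand_enumerated_fractions(self):
        """Four hand-listed samples at lambda = 10 000: NMB > 0 for exactly
        the two samples with dQALY 0.2/dCost 1000 and dQALY 0.1/dCost 500."""
        samples = self._samples(
            [(1000.0, 0.2), (500.0, 0.1), (2000.0, 0.1), (-100.0, -0.05)]
        )
        curve = g.ceac(samples, thresholds=[10_000.0])
        assert curve["p_trabeculectomy"].iloc[0] == pytest.approx(2 / 4)

    def test_lambda_zero_is_cost_saving_probability(self):
        samples = self._samples([(-10.0, 0.1), (5.0, 0.2), (-3.0, -0.1), (0.0, 0.3)])
        curve = g.ceac(samples, thresholds=[0.0])
        assert curve["p_trabeculectomy"].iloc[0] == pytest.approx(2 / 4)

    def test_tie_goes_to_medication(self):
        samples = self._samples([(2000.0, 0.1)])  # NMB exactly 0 at 20 000
        curve = g.ceac(samples, thresholds=[20_000.0])
        assert curve["p_trabeculectomy"].iloc[0] == 0.0

    def test_probabilities_sum_to_one_and_limits(self, estimated_params):
        samples = g.run_psa(estimated_params, n_iterations=100, seed=21, horizon=10)
        curve = g.ceac(samples)
        assert np.allclose(
            curve["p_trabeculectomy"] + curve["p_medication"], 1.0
        )
        assert curve["threshold"].iloc[0] == 0.0
        p_cost_saving = (samples["delta_cost"] < 0).mean()
        assert curve["p_trabeculectomy"].iloc[0] == pytest.approx(p_cost_saving)
        p_gain = (samples["delta_qaly"] > 0).mean()
        big = g.ceac(samples, thresholds=[1e9])
        assert big["p_trabeculectomy"].iloc[0] == pytest.approx(p_gain, abs=0.02)

    def test_identical_positive_nmb_samples_give_probability_one(self):
        samples = self._samples([(100.0, 0.5)] * 3)
        curve = g.ceac(samples, thresholds=[20_000.0])
        assert curve["p_trabeculectomy"].iloc[0] == 1.0

    def test_default_grid_includes_reporting_thresholds(self):
        for thr in (0.0, 10_000.0, 20_000.0, 50_000.0):
            assert thr in DEFAULT_LAMBDA_GRID


class TestCePlane:
    def test_isotropic_cloud_near_circular(self):
        rng = np.random.default_rng(31)
        pts = rng.standard_normal((10_000, 2))
        samples = pd.DataFrame(
            {"delta_qaly": pts[:, 0], "delta_cost": pts[:, 1], "iteration": range(len(pts))}
        )
        plane = g.ce_plane(samples)
        assert not plane.degenerate
        ratio = plane.axis_lengths[0] / plane.axis_lengths[1]
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_coverage_close_to_95_percent(self):
        rng = np.random.default_rng(17)
        cov = np.array([[0.02, 10.0], [10.0, 40_000.0]])
        L = np.linalg.cholesky(cov)
        pts = rng.standard_normal((10_000, 2)) @ L.T + np.array([0.3, 2500.0])
        samples = pd.DataFrame(
            {"delta_qaly": pts[:, 0], "delta_cost": pts[:, 1], "iteration": range(len(pts))}
        )
        plane = g.ce_plane(samples)
        inside = plane.contains(samples["delta_qaly"], samples["delta_cost"])
        assert inside.mean() == pytest.approx(0.95, abs=0.01)

    def test_degenerate_cloud_flagged(self):
        samples = pd.DataFrame(
            {"delta_qaly": [0.1] * 5, "delta_cost": [100.0] * 5, "iteration": range(5)}
        )
        plane = g.ce_plane(samples)
        assert plane.degenerate
        with pytest.raises(ValueError):
            plane.contains([0.1], [100.0])

    def test_too_few_samples_rejected(self):
        samples = pd.DataFrame(
            {"delta_qaly": [0.1], "delta_cost": [1.0], "iteration": [0]}
        )
        with pytest.raises(ValueError):
            g.ce_plane(samples)


class TestDeterministic:
    def test_equal_bounds_zero_width(self, truth_params):
        entry = g.one_way(truth_params, "discount_rate", 0.035, 0.035, horizon=10)
        assert entry.width == 0.0

    def test_discount_rate_outweighs_tiny_cost_perturbation(self, truth_params):
        wide = g.one_way(truth_params, "discount_rate", 0.0, 0.07)
        narrow = g.one_way(truth_params, "cost_scale", 0.99, 1.01)
        assert wide.width > narrow.width

    def test_tornado_sorted_descending(self, truth_params):
        table = g.tornado(
            truth_params,
            ranges={
                "discount_rate": (0.0, 0.07),
                "cost_scale": (0.99, 1.01),
                "smr_bilateral": (1.0, 2.0),
            },
            horizon=10,
        )
        widths = table["width"].to_numpy()
        assert (np.diff(widths) <= 1e-9).all()

    def test_default_ranges_respect_bounds(self, truth_params):
        ranges = default_tornado_ranges(truth_params)
        for pid, (lo, hi) in ranges.items():
            assert lo <= hi
            if pid.startswith("transition/"):
                assert 0.0 <= lo and hi <= 1.0
            if pid.startswith("smr"):
                assert lo >= 1.0

    def test_invalid_bounds_rejected(self, truth_params):
        with pytest.raises(ValueError):
            g.one_way(truth_params, "discount_rate", 0.07, 0.0)

    def test_scenario_horizons_costs_accrue_over_time(self, truth_params):
        from glaucoma_cea.states import ARM_TRAB

        tables = g.scenario_horizons(truth_params, instruments=("eq5d",))
        d_costs = {}
        for h, table in tables.items():
            trab = table[table["arm"] == ARM_TRAB].iloc[0]
            d_costs[h] = trab["dCost"]
        assert d_costs[2] <= d_costs[10] <= d_costs["lifetime"]
        lifetime = tables["lifetime"]
        assert set(lifetime.columns) == set(tables[2].columns)
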