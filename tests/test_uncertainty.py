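"""PSA distributions, Monte-Carlo propagation, CEAC, scenarios, tornado."""

import math

import numpy as np
import pandas as pd
import pytest

from cohortcea import (
    DistributionError,
    OutcomeSettings,
    ParameterDistribution,
    PathError,
    PSAError,
    PSAResult,
    ScenarioSpec,
    assign_parameter,
    ceac,
    evaluate_pair,
    fit_distribution_from_moments,
    one_way_tornado,
    resolve_parameter,
    run_psa,
    run_scenarios,
)

from .conftest import make_pair


class TestMomentFits:
    def test_beta_closed_form(self):
        params = fit_distribution_from_moments("beta", 0.5, 0.1)
        assert params["alpha"] == pytest.approx(12.0, abs=1e-12)
        assert params["beta"] == pytest.approx(12.0, abs=1e-12)

    def test_gamma_closed_form(self):
        params = fit_distribution_from_moments("gamma", 1000.0, 100.0)
        assert params["shape"] == pytest.approx(100.0, abs=1e-12)
        assert params["scale"] == pytest.approx(10.0, abs=1e-12)

    def test_lognormal_reproduces_moments_analytically(self):
        mu_target, se = 50.0, 12.0
        p = fit_distribution_from_moments("lognormal", mu_target, se)
        mean = math.exp(p["mu"] + p["sigma"] ** 2 / 2)
        var = (math.exp(p["sigma"] ** 2) - 1) * math.exp(2 * p["mu"] + p["sigma"] ** 2)
        assert mean == pytest.approx(mu_target, rel=1e-12)
        assert var == pytest.approx(se**2, rel=1e-12)

    def test_infeasible_beta_variance(self):
        with pytest.raises(DistributionError, match="[Ii]nfeasible"):
            fit_distribution_from_moments("beta", 0.5, 0.6)

    @pytest.mark.parametrize("family", ["beta", "gamma", "lognormal", "normal"])
    def test_sampling_recovers_moments(self, family):
        """Empirical mean/SD over many draws match the request within
        3 Monte-Carlo standard errors."""
        mean, se = (0.4, 0.08) if family == "beta" else (800.0, 120.0)
        dist = ParameterDistribution(target="intervention_cost.one_off",
                                     family=family, mean=mean, se=se)
        rng = np.random.default_rng(7)
        n = 100_000
        draws = np.array([dist.sample(rng) for _ in range(n)])
        assert draws.mean() == pytest.approx(mean, abs=3 * se / math.sqrt(n))
        assert draws.std(ddof=1) == pytest.approx(se, abs=3 * se / math.sqrt(2 * n))

    def test_truncation_enforced_by_rejection(self):
        dist = ParameterDistribution(
            target="intervention_cost.one_off", family="normal",
            mean=100.0, se=50.0, truncation=(50.0, 150.0),
        )
        rng = np.random.default_rng(3)
        draws = [dist.sample(rng) for _ in range(2000)]
        assert min(draws) >= 50.0 and max(draws) <= 150.0


class TestParameterPaths:
    def test_resolve_and_assign(self, simple_pair):
        path = "control.transition.baseline.deteriorated"
        assert resolve_parameter(simple_pair, path) == 0.10
        assign_parameter(simple_pair, path, 0.2)
        assert simple_pair.control.find_transition("baseline", "deteriorated").value == 0.2
        assert simple_pair.intervention.find_transition("baseline", "deteriorated").value == 0.06

    def test_both_arm_assignment(self, simple_pair):
        assign_parameter(simple_pair, "both.utility.deteriorated", 0.5)
        assert simple_pair.control.state_values["deteriorated"].utility == 0.5
        assert simple_pair.intervention.state_values["deteriorated"].utility == 0.5

    def test_dangling_path(self, simple_pair):
        with pytest.raises(PathError, match="frail"):
            resolve_parameter(simple_pair, "control.utility.frail")
        with pytest.raises(PathError):
            resolve_parameter(simple_pair, "control.transition.baseline.frail")

    def test_domain_enforced_on_assignment(self, simple_pair):
        from cohortcea import ModelValidationError

        with pytest.raises(ModelValidationError, match="domain"):
            assign_parameter(
                simple_pair, "control.transition.baseline.deteriorated", 1.4
            )
        with pytest.raises(ModelValidationError, match="domain"):
            assign_parameter(simple_pair, "control.cost_healthcare.baseline", -5.0)

    def test_beta_on_cost_target_rejected(self, simple_pair):
        dist = ParameterDistribution(
            target="control.cost_healthcare.deteriorated",
            family="beta", mean=0.5, se=0.1,
        )
        with pytest.raises(DistributionError, match="beta"):
            run_psa(simple_pair, [dist], 5, 1, OutcomeSettings(horizon_cycles=10))


def base_distributions(pair):
    return [
        ParameterDistribution(
            target="control.transition.baseline.deteriorated",
            family="beta", mean=0.10, se=0.02,
        ),
        ParameterDistribution(
            target="both.utility.deteriorated", family="beta", mean=0.60, se=0.05,
        ),
        ParameterDistribution(
            target="control.cost_healthcare.deteriorated",
            family="gamma", mean=3000.0, se=400.0,
        ),
    ]


class TestRunPSA:
    def settings(self):
        return OutcomeSettings(horizon_cycles=15)

    def test_all_fixed_equals_deterministic(self, simple_pair):
        deterministic = evaluate_pair(simple_pair, self.settings()).incremental
        fixed = [
            ParameterDistribution(
                target=path, family="fixed",
                mean=resolve_parameter(simple_pair, path),
            )
            for path in (
                "control.transition.baseline.deteriorated",
                "both.utility.deteriorated",
                "intervention_cost.one_off",
            )
        ]
        result = run_psa(simple_pair, fixed, 7, 123, self.settings())
        assert (result.draws["delta_e"] == deterministic.delta_e).all()
        assert (result.draws["delta_c"] == deterministic.delta_c).all()
        assert (result.draws["inmb"] == deterministic.inmb).all()

    def test_seed_reproducibility_bitwise(self, simple_pair):
        dists = base_distributions(simple_pair)
        a = run_psa(simple_pair, dists, 50, 99, self.settings())
        b = run_psa(simple_pair, dists, 50, 99, self.settings())
        pd.testing.assert_frame_equal(a.draws, b.draws, check_exact=True)
        c = run_psa(simple_pair, dists, 50, 100, self.settings())
        assert not a.draws.equals(c.draws)

    def test_sampled_column_recovers_beta_mean(self, simple_pair):
        dists = [
            ParameterDistribution(
                target="both.utility.deteriorated", family="beta",
                params={"alpha": 12.0, "beta": 12.0},
            )
        ]
        result = run_psa(simple_pair, dists, 10_000, 5, self.settings())
        col = result.draws["both.utility.deteriorated"]
        assert col.mean() == pytest.approx(0.5, abs=3 * col.std() / math.sqrt(10_000))

    def test_base_pair_is_not_mutated(self, simple_pair):
        before = simple_pair.control.model_dump()
        run_psa(simple_pair, base_distributions(simple_pair), 20, 1, self.settings())
        assert simple_pair.control.model_dump() == before

    def test_rejection_cap_aborts_with_diagnostic(self, simple_pair):
        # half the draws exceed the probability domain -> rejection rate >> cap
        bad = ParameterDistribution(
            target="control.transition.baseline.deteriorated",
            family="normal", mean=0.9, se=0.6,
        )
        with pytest.raises(PSAError, match="control.transition.baseline.deteriorated"):
            run_psa(simple_pair, [bad], 200, 11, self.settings())

    def test_dangling_target_fails_fast(self, simple_pair):
        bad = ParameterDistribution(
            target="control.utility.frail", family="beta", mean=0.5, se=0.1
        )
        with pytest.raises(PathError):
            run_psa(simple_pair, [bad], 5, 1, self.settings())


def synthetic_result(delta_e, delta_c):
    draws = pd.DataFrame(
        {"delta_e": delta_e, "delta_c": delta_c,
         "inmb": np.zeros(len(delta_e))}
    )
    return PSAResult(draws=draws, n_draws=len(delta_e), seed=0, wtp_lambda=30000.0)


class TestCEAC:
    def test_dominant_draws_probability_one(self):
        res = synthetic_result([0.1, 0.2, 0.3], [-10.0, -20.0, -5.0])
        curve = ceac(res, [1000.0, 50000.0])
        assert (curve["probability"] == 1.0).all()

    def test_dominated_draws_probability_zero(self):
        res = synthetic_result([-0.1, -0.2], [10.0, 20.0])
        curve = ceac(res, [1000.0, 50000.0])
        assert (curve["probability"] == 0.0).all()

    def test_counting_is_exact(self):
        # at λ=10000: INMB = ±1000 split 50/50
        de = [0.2] * 50 + [0.2] * 50
        dc = [1000.0] * 50 + [3000.0] * 50
        curve = ceac(synthetic_result(de, dc), [10_000.0])
        assert curve["probability"].iloc[0] == 0.5

    def test_limits(self):
        """λ→0 recovers the cost-saving fraction, λ→∞ the effect-positive one."""
        de = [0.5, 0.5, -0.5, -0.5]
        dc = [-100.0, 200.0, -300.0, 400.0]
        res = synthetic_result(de, dc)
        low = ceac(res, [0.0])["probability"].iloc[0]
        assert low == 0.5  # exactly the draws with delta_c < 0
        high = ceac(res, [1e12])["probability"].iloc[0]
        assert high == 0.5  # exactly the draws with delta_e > 0

    def test_monotone_in_lambda_when_effects_nonnegative(self, simple_pair, rng):
        de = rng.uniform(0.0, 1.0, 200)
        dc = rng.normal(500.0, 800.0, 200)
        curve = ceac(synthetic_result(de, dc), np.linspace(0, 80000, 33))
        assert (np.diff(curve["probability"]) >= 0).all()

    def test_ties_count_as_not_cost_effective(self):
        curve = ceac(synthetic_result([0.0], [0.0]), [30000.0])
        assert curve["probability"].iloc[0] == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(PSAError, match="empty"):
            ceac(synthetic_result([0.1], [1.0]), [])


class TestScenarios:
    def settings(self):
        return OutcomeSettings(horizon_cycles=15)

    def test_base_case_included_first_and_empty_override_matches(self, simple_pair):
        table = run_scenarios(
            simple_pair, [ScenarioSpec(name="noop")], self.settings()
        )
        assert list(table["scenario"]) == ["base_case", "noop"]
        assert table.loc[0, "inmb"] == table.loc[1, "inmb"]

    def test_larger_utility_gap_increases_delta_e(self, simple_pair):
        # widening the utility decrement makes avoided incidence worth more
        sc = ScenarioSpec(name="worse_state", overrides={"both.utility.deteriorated": 0.4})
        table = run_scenarios(simple_pair, [sc], self.settings())
        assert table.loc[1, "delta_e"] > table.loc[0, "delta_e"]

    def test_lambda_only_scenarios_shift_inmb_linearly(self, simple_pair):
        s1 = ScenarioSpec(name="l1", overrides={"settings.lambda": 20000.0})
        s2 = ScenarioSpec(name="l2", overrides={"settings.lambda": 50000.0})
        table = run_scenarios(simple_pair, [s1, s2], self.settings())
        assert table.loc[1, "delta_e"] == table.loc[2, "delta_e"]
        assert table.loc[1, "delta_c"] == table.loc[2, "delta_c"]
        expected = table.loc[1, "delta_e"] * 30000.0
        assert table.loc[2, "inmb"] - table.loc[1, "inmb"] == pytest.approx(expected)

    def test_unresolvable_override_names_scenario(self, simple_pair):
        sc = ScenarioSpec(name="broken", overrides={"control.utility.frail": 0.5})
        with pytest.raises(PathError, match="broken"):
            run_scenarios(simple_pair, [sc], self.settings())


class TestTornado:
    def settings(self):
        return OutcomeSettings(horizon_cycles=15)

    def test_ranges_sorted_non_increasing(self, simple_pair):
        table = one_way_tornado(
            simple_pair, base_distributions(simple_pair), self.settings()
        )
        ranges = table["inmb_range"].to_numpy()
        assert (np.diff(ranges) <= 1e-12).all()

    def test_fixed_at_zero_has_zero_range(self, simple_pair):
        dist = ParameterDistribution(
            target="intervention_cost.per_cycle", family="fixed", mean=0.0
        )
        table = one_way_tornado(simple_pair, [dist], self.settings())
        assert table["inmb_range"].iloc[0] == 0.0

    def test_fixed_uses_plus_minus_twenty_percent(self, simple_pair):
        pair = make_pair(one_off=1000.0)
        dist = ParameterDistribution(
            target="intervention_cost.one_off", family="fixed", mean=1000.0
        )
        table = one_way_tornado(pair, [dist], self.settings())
        assert table["low_value"].iloc[0] == pytest.approx(800.0)
        assert table["high_value"].iloc[0] == pytest.approx(1200.0)
        # INMB is linear in a one-off cost: excursions are symmetric
        row = table.iloc[0]
        assert row["inmb_high"] - row["inmb_base"] == pytest.approx(
            row["inmb_base"] - row["inmb_low"], rel=1e-9
        )

    def test_symmetric_distribution_on_linear_parameter(self, simple_pair):
        # INMB is linear in a per-state cost, so a symmetric (normal)
        # distribution produces symmetric INMB excursions about base
        dist = ParameterDistribution(
            target="control.cost_healthcare.deteriorated",
            family="normal", mean=3000.0, se=300.0,
        )
        table = one_way_tornado(simple_pair, [dist], self.settings())
        row = table.iloc[0]
        assert row["inmb_high"] - row["inmb_base"] == pytest.approx(
            row["inmb_base"] - row["inmb_low"], rel=1e-6
        )

    def test_percentiles_clamped_to_domain(self, simple_pair, caplog):
        import logging

        dist = ParameterDistribution(
            target="control.cost_healthcare.deteriorated",
            family="normal", mean=200.0, se=400.0,
        )
        with caplog.at_level(logging.WARNING):
            table = one_way_tornado(simple_pair, [dist], self.settings())
        assert table["low_value"].iloc[0] == 0.0
        assert any("clamped" in rec.message for rec in caplog.records)
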