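"""Moment matching, PSA determinism, CEAC/CEAF, threshold bisection."""

import math

import numpy as np
import pandas as pd
import pytest

import ipfcea as m
from ipfcea.parameters import ConfigError
from ipfcea.sensitivity import (
    ParameterDistribution,
    PSAResult,
    apply_values,
    ceac_ceaf,
    moment_match,
    run_psa,
    sample_distribution,
    table1_distributions,
    threshold_search,
)

from conftest import zero_sd_inputs


class TestMomentMatch:
    def test_beta_roundtrip_worst_band_utility(self):
        alpha, beta = moment_match(ParameterDistribution("u", "beta", 0.6634, 0.2552))
        mean = alpha / (alpha + beta)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert mean == pytest.approx(0.6634, abs=1e-10)
        assert math.sqrt(var) == pytest.approx(0.2552, abs=1e-10)

    def test_lognormal_roundtrip_exacerbation_cost(self):
        mu, sigma = moment_match(ParameterDistribution("c", "lognormal", 14_731.0, 4_026.0))
        mean = math.exp(mu + sigma**2 / 2)
        sd = math.sqrt((math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2))
        assert mean == pytest.approx(14_731.0, rel=1e-10)
        assert sd == pytest.approx(4_026.0, rel=1e-10)

    def test_zero_sd_is_point_mass(self):
        d = ParameterDistribution("x", "beta", 0.5, 0.0)
        assert moment_match(d) is None
        rng = np.random.default_rng(0)
        assert sample_distribution(d, rng) == 0.5
        assert np.all(sample_distribution(d, rng, size=4) == 0.5)

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ConfigError, match="infeasible"):
            moment_match(ParameterDistribution("u", "beta", 0.5, 0.6))

    def test_sampled_values_respect_support(self):
        rng = np.random.default_rng(1)
        b = sample_distribution(ParameterDistribution("u", "beta", 0.838, 0.1782), rng, 2_000)
        assert np.all((b > 0) & (b < 1))
        ln = sample_distribution(ParameterDistribution("c", "lognormal", 0.55, 0.09), rng, 2_000)
        assert np.all(ln > 0)
        assert ln.mean() == pytest.approx(0.55, rel=0.05)


class TestRunPsa:
    def test_base_case_distribution_set(self, base_inputs):
        ds = table1_distributions(base_inputs)
        targets = {d.target for d in ds}
        assert "utility:90-110" in targets and "or_exacerbation:nintedanib" in targets
        assert "annual_drug_cost:pirfenidone" not in targets  # prices have no printed sd
        families = {d.target: d.family for d in ds}
        assert families["utility:40-49.9"] == "beta"
        assert families["ae_episode_cost"] == "lognormal"
        # symptom management carries no uncertain odds ratios
        assert not any(t.endswith(":symptom_management") for t in targets)

    def test_all_sds_zero_reproduces_base_case(self, base_inputs):
        inputs0 = zero_sd_inputs(base_inputs)
        assert table1_distributions(inputs0) == []
        base = [m.lifetime_outcomes(s, inputs0) for s in inputs0.strategies]
        res = run_psa(inputs0, n=4, seed=9)
        for j, out in enumerate(base):
            assert np.all(res.costs[:, j] == out.cost)
            assert np.all(res.qalys[:, j] == out.qalys)

    def test_same_seed_reproducible(self, base_inputs):
        a = run_psa(base_inputs, n=40, seed=123)
        b = run_psa(base_inputs, n=40, seed=123)
        assert np.array_equal(a.costs, b.costs) and np.array_equal(a.qalys, b.qalys)

    def test_ceac_rows_sum_to_one(self, base_inputs):
        res = run_psa(base_inputs, n=150, seed=2)
        ceac, ceaf = ceac_ceaf(res, m.default_wtp_grid())
        np.testing.assert_allclose(ceac.sum(axis=1).to_numpy(), 1.0, atol=1e-12)
        # CEAF strategy has maximal mean NMB at each grid point, checked directly
        for wtp in (0.0, 1e6, 3e6):
            mean_nmb = (res.qalys * wtp - res.costs).mean(axis=0)
            assert ceaf.loc[wtp] == res.names[int(np.argmax(mean_nmb))]


class TestCeacCeaf:
    def _manual_result(self, costs, qalys, names=("A", "B")):
        costs = np.asarray(costs, dtype=float)
        qalys = np.asarray(qalys, dtype=float)
        return PSAResult(tuple(names), costs, qalys, costs.shape[0], seed=None)

    def test_single_strategy_is_always_accepted(self):
        res = self._manual_result([[1.0], [2.0]], [[1.0], [1.5]], names=("only",))
        ceac, ceaf = ceac_ceaf(res, [0.0, 1e5])
        assert np.all(ceac["only"].to_numpy() == 1.0)
        assert set(ceaf) == {"only"}

    def test_four_draw_enumeration(self):
        # at WTP 10: draw NMBs A: 10,10,0,20 / B: 12,8,0,15 -> B,A,tie,A
        res = self._manual_result(
            costs=[[0.0, 8.0], [0.0, 12.0], [10.0, 10.0], [0.0, 5.0]],
            qalys=[[1.0, 2.0], [1.0, 2.0], [1.0, 1.0], [2.0, 2.0]],
        )
        ceac, ceaf = ceac_ceaf(res, [10.0])
        assert ceac.loc[10.0, "A"] == pytest.approx((0 + 1 + 0.5 + 1) / 4)
        assert ceac.loc[10.0, "B"] == pytest.approx((1 + 0 + 0.5 + 0) / 4)
        assert ceaf.loc[10.0] == "A"  # mean NMB 10 vs 8.75

    def test_zero_variance_draws_step_at_deterministic_icer(self):
        res = self._manual_result(
            costs=[[0.0, 100.0]] * 3, qalys=[[1.0, 2.0]] * 3
        )  # ICER of B vs A = 100
        ceac, _ = ceac_ceaf(res, [0.0, 50.0, 99.0, 101.0, 1000.0])
        assert list(ceac["B"]) == [0.0, 0.0, 0.0, 1.0, 1.0]

    def test_more_effective_strategy_curve_monotone_when_qalys_ordered(self):
        rng = np.random.default_rng(3)
        qal_a = rng.uniform(1, 2, 200)
        res = self._manual_result(
            costs=np.column_stack([rng.uniform(0, 10, 200), rng.uniform(50, 150, 200)]),
            qalys=np.column_stack([qal_a, qal_a + rng.uniform(0.1, 0.5, 200)]),
        )
        ceac, _ = ceac_ceaf(res, np.linspace(0, 2000, 41))
        assert np.all(np.diff(ceac["B"].to_numpy()) >= 0.0)


class TestThresholdSearch:
    def test_bisection_recovers_analytic_switch_point(self, base_inputs):
        target = 1_234.5678

        def chooser(v):
            return "low" if v < target else "high"

        res = threshold_search(
            base_inputs, "annual_drug_cost:nintedanib", (0.0, 10_000.0),
            rel_tol=1e-6, chooser=chooser,
        )
        assert res.value == pytest.approx(target, rel=1e-4)
        assert (res.strategy_below, res.strategy_above) == ("low", "high")

    def test_drug_price_threshold_matches_linear_closed_form(self, base_inputs):
        # lifetime cost is exactly linear in annual price, so the WTP-100k
        # switch point has the closed form (wtp*dQ - dC0) / drug-years
        wtp = base_inputs.globals.wtp
        ref = m.lifetime_outcomes(base_inputs.reference_strategy(), base_inputs)
        at0 = apply_values(base_inputs, {"annual_drug_cost:nintedanib": 0.0})
        at1 = apply_values(base_inputs, {"annual_drug_cost:nintedanib": 1.0})
        c0 = m.lifetime_outcomes(at0.strategy("nintedanib"), at0)
        c1 = m.lifetime_outcomes(at1.strategy("nintedanib"), at1)
        drug_years = c1.cost - c0.cost  # discounted drug-exposure years
        analytic = (wtp * (c0.qalys - ref.qalys) - (c0.cost - ref.cost)) / drug_years
        res = threshold_search(
            base_inputs, "annual_drug_cost:nintedanib", (0.0, 112_357.0), rel_tol=1e-6
        )
        assert res.found
        assert res.value == pytest.approx(analytic, rel=1e-4)
        assert res.strategy_below == "nintedanib"
        assert res.strategy_above == "symptom_management"

    def test_no_switch_reported_not_raised(self, base_inputs):
        res = threshold_search(base_inputs, "annual_drug_cost:nintedanib", (0.0, 1_000.0))
        assert not res.found
        assert res.strategy_below == res.strategy_above == "nintedanib"

    def test_multiple_switches_violate_precondition(self, base_inputs):
        def chooser(v):
            return "A" if 2.0 < v < 8.0 else "B"

        with pytest.raises(RuntimeError, match="more than once"):
            threshold_search(
                base_inputs, "annual_drug_cost:nintedanib", (0.0, 10.0), chooser=chooser
            )


class TestApplyValues:
    def test_moves_only_the_targeted_mean(self, base_inputs):
        out = apply_values(base_inputs, {"utility:90-110": 0.9, "or_mortality:nintedanib": 0.8})
        assert out.states[0].utility_mean == 0.9
        assert out.states[0].utility_sd == base_inputs.states[0].utility_sd
        assert out.strategy("nintedanib").or_mortality.mean == 0.8
        assert out.strategy("pirfenidone") == base_inputs.strategy("pirfenidone")

    def test_unknown_path_rejected(self, base_inputs):
        with pytest.raises(ConfigError, match="unknown parameter path"):
            apply_values(base_inputs, {"nonsense": 1.0})

    def test_invalid_value_rejected(self, base_inputs):
        with pytest.raises(ConfigError):
            apply_values(base_inputs, {"utility:90-110": 1.5})
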