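"""Frontier, net monetary benefit, sensitivity analyses, PSA."""

import numpy as np
import pytest

from nutricea.cea import (CEAConfig, CEAValidationError, ParamDistribution,
                          acceptability_report, default_psa_distributions,
                          icer_frontier, net_monetary_benefit,
                          one_way_sensitivity, run_psa)
from nutricea.markov import MarkovSpec, StrategyResult, run_cohort

TABLE = [StrategyResult("ONS", 27_753.0, 4.53),
         StrategyResult("NTF", 28_691.0, 5.06),
         StrategyResult("PEG", 35_148.0, 6.93)]


class TestFrontier:
    def test_published_cost_qaly_triple(self):
        """Sequential ICERs recomputed from the published (cost, QALY) rows."""
        fr = icer_frontier(TABLE)
        assert fr.frontier_labels == ["ONS", "NTF", "PEG"]
        assert fr.sequential_icers["NTF"] == pytest.approx(1769.81, abs=0.01)
        assert fr.sequential_icers["PEG"] == pytest.approx(3452.94, abs=0.01)

    def test_strong_dominance(self):
        results = TABLE + [StrategyResult("bad", 40_000.0, 4.0)]
        fr = icer_frontier(results)
        assert fr.strongly_dominated["bad"]
        assert not fr.on_frontier["bad"]
        assert "bad" not in fr.sequential_icers

    def test_extended_dominance(self):
        # middle strategy's ICER (2000) exceeds the next one's (1000)
        results = [StrategyResult("a", 0.0, 0.0),
                   StrategyResult("b", 2_000.0, 1.0),
                   StrategyResult("c", 4_000.0, 3.0)]
        fr = icer_frontier(results)
        assert fr.extendedly_dominated["b"]
        assert fr.frontier_labels == ["a", "c"]
        icers = [fr.sequential_icers[lbl] for lbl in fr.frontier_labels[1:]]
        assert icers == sorted(icers)

    def test_sequential_icers_strictly_increase(self, frontier_oracle):
        rng = np.random.default_rng(1)
        for _ in range(20):
            results = [StrategyResult(f"s{i}", rng.uniform(0, 50_000),
                                      rng.uniform(0, 10)) for i in range(5)]
            fr = icer_frontier(results)
            icers = [fr.sequential_icers[lbl] for lbl in fr.frontier_labels[1:]]
            assert all(x < y for x, y in zip(icers, icers[1:]))

    def test_matches_nmb_sweep_oracle_on_random_instances(self, frontier_oracle):
        rng = np.random.default_rng(42)
        for _ in range(150):
            results = [StrategyResult(f"s{i}", rng.uniform(0, 50_000),
                                      rng.uniform(0, 10)) for i in range(5)]
            fr = icer_frontier(results)
            assert set(fr.frontier_labels) == frontier_oracle(results)

    def test_exact_ties_are_flagged(self):
        results = [StrategyResult("a", 100.0, 1.0),
                   StrategyResult("b", 100.0, 1.0)]
        fr = icer_frontier(results)
        assert fr.tie_flagged
        # tie broken by label order: 'a' first
        assert fr.ordered_strategies[0].strategy_label == "a"

    def test_needs_two_distinct_strategies(self):
        with pytest.raises(CEAValidationError):
            icer_frontier([TABLE[0]])
        with pytest.raises(CEAValidationError):
            icer_frontier([TABLE[0], TABLE[0]])


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(TABLE[0], 0.0) == -27_753.0

    def test_published_values_at_5000(self):
        nmbs = {r.strategy_label: net_monetary_benefit(r, 5_000.0)
                for r in TABLE}
        assert nmbs["PEG"] == pytest.approx(-498.0)
        assert nmbs["NTF"] == pytest.approx(-3_391.0)
        assert nmbs["ONS"] == pytest.approx(-5_103.0)
        assert max(nmbs, key=nmbs.get) == "PEG"

    def test_linear_in_wtp_with_slope_qalys(self):
        r = TABLE[2]
        for w in (0.0, 1_000.0, 20_000.0):
            assert net_monetary_benefit(r, w + 1.0) - net_monetary_benefit(r, w) \
                == pytest.approx(r.total_qalys)

    def test_smallest_threshold_where_peg_wins_is_5000(self):
        winners = {}
        for w in range(0, 50_001, 5_000):
            nmbs = {r.strategy_label: net_monetary_benefit(r, float(w))
                    for r in TABLE}
            winners[w] = max(nmbs, key=nmbs.get)
        peg_thresholds = [w for w, s in winners.items() if s == "PEG"]
        assert min(peg_thresholds) == 5_000

    def test_negative_wtp_rejected(self):
        with pytest.raises(CEAValidationError):
            net_monetary_benefit(TABLE[0], -1.0)


def simple_specs():
    base = np.array([[0.8, 0.1, 0.1], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]])
    a = MarkovSpec(transitions=base.copy(), state_costs=[500, 8000, 0],
                   one_time_cost=10_000, horizon_cycles=15, label="A")
    better = np.array([[0.9, 0.05, 0.05], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]])
    b = MarkovSpec(transitions=better, state_costs=[500, 8000, 0],
                   one_time_cost=15_000, horizon_cycles=15, label="B")
    return {"A": a, "B": b}


class TestOneWay:
    def test_irrelevant_parameter_has_zero_swing(self):
        specs = simple_specs()
        # neither strategy's death state accrues cost or utility
        tor = one_way_sensitivity(specs, {"state_costs.death": (0.0, 0.0)},
                                  ("A", "B"))
        assert tor["swing"].iloc[0] == pytest.approx(0.0)

    def test_one_time_cost_shift_is_closed_form(self):
        specs = simple_specs()
        _, ra = run_cohort(specs["A"])
        _, rb = run_cohort(specs["B"])
        dq = rb.total_qalys - ra.total_qalys
        base = (rb.total_cost - ra.total_cost) / dq
        tor = one_way_sensitivity(
            specs, {"B:one_time_cost": (10_000.0, 30_000.0)}, ("A", "B"))
        row = tor.iloc[0]
        assert row["icer_at_low"] == pytest.approx(base - 5_000.0 / dq)
        assert row["icer_at_high"] == pytest.approx(base + 15_000.0 / dq)

    def test_row_order_is_by_swing_not_input_order(self):
        specs = simple_specs()
        ranges = {"state_costs.death": (0.0, 0.0),
                  "B:one_time_cost": (10_000.0, 30_000.0),
                  "utilities.disease_free": (0.7, 0.9)}
        tor1 = one_way_sensitivity(specs, ranges, ("A", "B"))
        tor2 = one_way_sensitivity(specs, dict(reversed(list(ranges.items()))),
                                   ("A", "B"))
        assert list(tor1["parameter"]) == list(tor2["parameter"])
        assert tor1["swing"].is_monotonic_decreasing

    def test_range_must_contain_base_value(self):
        specs = simple_specs()
        with pytest.raises(CEAValidationError):
            one_way_sensitivity(specs, {"B:one_time_cost": (0.0, 100.0)},
                                ("A", "B"))


class TestDistributions:
    def test_family_constraints(self):
        with pytest.raises(CEAValidationError):
            ParamDistribution("utilities.relapse", "beta", 1.3, 0.1)
        with pytest.raises(CEAValidationError):
            ParamDistribution("one_time_cost", "gamma", -5.0, 0.1)
        with pytest.raises(CEAValidationError):
            ParamDistribution("one_time_cost", "lognormal", 5.0, 0.1)

    def test_method_of_moments(self):
        beta = ParamDistribution("utilities.relapse", "beta", 0.53, 0.10)
        u = np.linspace(0.0005, 0.9995, 2_000)
        draws = np.array([beta.ppf(x) for x in u])
        assert draws.mean() == pytest.approx(0.53, abs=0.01)
        assert draws.std() == pytest.approx(0.053, abs=0.005)
        gamma = ParamDistribution("one_time_cost", "gamma", 10_000.0, 0.30)
        draws = np.array([gamma.ppf(x) for x in u])
        assert draws.mean() == pytest.approx(10_000.0, rel=0.02)

    def test_fixed_family_is_point_mass(self):
        fixed = ParamDistribution("one_time_cost", "fixed", 7.0, 0.0)
        assert fixed.ppf(0.01) == fixed.ppf(0.99) == 7.0


class TestPSA:
    def test_all_fixed_reproduces_deterministic_results(self):
        specs = simple_specs()
        config = CEAConfig(psa_draws=20, seed=1)
        dists = [ParamDistribution("one_time_cost", "fixed",
                                   specs["A"].one_time_cost, 0.0, strategy="A")]
        psa = run_psa(specs, dists, config)
        for lbl, spec in specs.items():
            _, det = run_cohort(spec)
            assert np.allclose(psa.draws[lbl][:, 0], det.total_cost)
            assert np.allclose(psa.draws[lbl][:, 1], det.total_qalys)
        # degenerate CEAC: all mass on the NMB maximizer at each threshold
        assert set(np.unique(psa.ceac.to_numpy())) <= {0.0, 1.0}

    def test_ceac_rows_sum_to_one(self):
        specs = simple_specs()
        config = CEAConfig(psa_draws=100, seed=2)
        psa = run_psa(specs, default_psa_distributions(specs, config), config)
        assert np.allclose(psa.ceac.sum(axis=1), 1.0, atol=1e-12)

    def test_seeded_reproducibility(self):
        specs = simple_specs()
        config = CEAConfig(psa_draws=50, seed=3)
        dists = default_psa_distributions(specs, config)
        a = run_psa(specs, dists, config)
        b = run_psa(specs, dists, config)
        for lbl in specs:
            assert np.array_equal(a.draws[lbl], b.draws[lbl])
        assert a.ceac.equals(b.ceac)

    def test_halving_draws_stays_within_binomial_noise(self):
        specs = simple_specs()
        dists_cfg = CEAConfig(psa_draws=1_200, seed=4)
        dists = default_psa_distributions(specs, dists_cfg)
        full = run_psa(specs, dists, dists_cfg)
        half = run_psa(specs, dists, CEAConfig(psa_draws=600, seed=5))
        for lbl in specs:
            p_full = full.ceac[lbl].to_numpy()
            p_half = half.ceac[lbl].to_numpy()
            se = np.sqrt(np.maximum(p_full * (1 - p_full), 1e-4) / 600)
            assert np.all(np.abs(p_full - p_half) <= 3.5 * se)


class TestAcceptabilityReport:
    def test_degenerate_psa_prefers_nmb_maximizer_with_probability_one(self):
        specs = simple_specs()
        config = CEAConfig(psa_draws=10, seed=0)
        dists = [ParamDistribution("one_time_cost", "fixed",
                                   specs["A"].one_time_cost, 0.0, strategy="A")]
        psa = run_psa(specs, dists, config)
        report = acceptability_report(psa, config)
        for col in ("p_cost_effective_at_10000", "p_cost_effective_at_50000"):
            assert report[col].sum() == pytest.approx(1.0)
            assert report[col].max() == pytest.approx(1.0)
        assert report["preferred_at_threshold"].sum() == 1

    def test_probabilities_sum_to_one_at_each_threshold(self):
        specs = simple_specs()
        config = CEAConfig(psa_draws=80, seed=6)
        psa = run_psa(specs, default_psa_distributions(specs, config), config)
        report = acceptability_report(psa, config)
        for col in ("p_cost_effective_at_10000", "p_cost_effective_at_50000"):
            assert report[col].sum() == pytest.approx(1.0)
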