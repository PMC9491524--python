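"""ICER classification, Monte-Carlo engine and scenario machinery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from msltcea.cea_engine import (ICER, IterationResult, PipelineInputs,
                                ScenarioConfig, default_cost_items,
                                default_inputs, default_scenarios, icer,
                                pooled_effects, proportion_cost_effective,
                                run_iteration, run_monte_carlo, run_scenarios,
                                write_results)


class TestICER:
    def test_cost_saving_health_gaining_is_dominant(self):
        assert icer(-710_000.0, 204.15).kind == "dominant"

    def test_positive_quadrant_reports_ratio(self):
        out = icer(1_130_000.0, 84.83)
        assert out.kind == "ratio"
        assert out.value == pytest.approx(13_320, abs=5)

    def test_costlier_and_harmful_is_dominated(self):
        assert icer(1000.0, -2.0).kind == "dominated"

    def test_degenerate_zero_pairs(self):
        with pytest.warns(RuntimeWarning):
            assert icer(0.0, 0.0).kind == "indeterminate"
        with pytest.warns(RuntimeWarning):
            assert icer(5.0, 0.0).value == np.inf


def _fake_iter(i, net, halys):
    return IterationResult(i, max(net, 0.0), min(net, 0.0) if net < 0 else 0.0,
                           halys, icer(net, halys))


class TestProportions:
    def test_known_composition(self):
        its = ([_fake_iter(i, -1.0, 1.0) for i in range(6)]          # dominant
               + [_fake_iter(i, 50_000.0, 1.0) for i in range(3)]    # 50k/HALY
               + [_fake_iter(i, 200_000.0, 1.0) for i in range(1)])  # 200k/HALY
        assert proportion_cost_effective(its, 65_000.0) == pytest.approx(0.9)

    def test_all_dominant(self):
        its = [_fake_iter(i, -1.0, 1.0) for i in range(5)]
        assert proportion_cost_effective(its, 65_000.0) == 1.0

    def test_zero_threshold_counts_only_dominant(self):
        its = [_fake_iter(0, -1.0, 1.0), _fake_iter(1, 10.0, 1.0)]
        assert proportion_cost_effective(its, 0.0) == 0.5


class TestIteration:
    def test_same_seed_identical_result(self, inputs):
        a = run_iteration(inputs, ScenarioConfig(), np.random.default_rng(42))
        b = run_iteration(inputs, ScenarioConfig(), np.random.default_rng(42))
        assert a == b

    def test_deterministic_mode_reproducible_and_point_valued(self, inputs):
        a = run_iteration(inputs, ScenarioConfig(), np.random.default_rng(0),
                          deterministic=True)
        b = run_iteration(inputs, ScenarioConfig(), np.random.default_rng(99),
                          deterministic=True)
        assert a == b  # rng is unused when distributions collapse
        det_cost = sum(i.mean * (3 if i.per_wave else 1)
                       for i in default_cost_items())
        assert a.intervention_cost == pytest.approx(det_cost)

    def test_null_effects_propagate_to_zero(self, inputs):
        null = PipelineInputs(inputs.population, inputs.diseases,
                              meta_results=[])  # nothing significant
        with pytest.warns(RuntimeWarning):  # zero-HALY ICER denominator
            it = run_iteration(null, ScenarioConfig(), np.random.default_rng(1))
        assert it.halys == 0.0 and it.healthcare_cost_diff == 0.0
        assert it.net_cost == it.intervention_cost

    def test_net_cost_identity(self, inputs):
        it = run_iteration(inputs, ScenarioConfig(), np.random.default_rng(2))
        assert it.net_cost == it.intervention_cost + it.healthcare_cost_diff


class TestMonteCarlo:
    def test_two_iterations_ui_is_min_max(self, inputs):
        res = run_monte_carlo(inputs, ScenarioConfig(), n=2, seed=3)
        costs = [it.intervention_cost for it in res.iterations]
        assert res.summary.loc["intervention_cost", "ui_lower"] == min(costs)
        assert res.summary.loc["intervention_cost", "ui_upper"] == max(costs)

    def test_master_seed_reproducibility(self, inputs):
        a = run_monte_carlo(inputs, ScenarioConfig(), n=8, seed=7)
        b = run_monte_carlo(inputs, ScenarioConfig(), n=8, seed=7)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        pd.testing.assert_frame_equal(a.ce_plane, b.ce_plane)
        assert a.iterations == b.iterations

    def test_ui_contains_deterministic_point(self, inputs):
        res = run_monte_carlo(inputs, ScenarioConfig(), n=60, seed=11)
        det = run_iteration(inputs, ScenarioConfig(), np.random.default_rng(0),
                            deterministic=True)
        s = res.summary
        assert s.loc["halys", "ui_lower"] <= det.halys <= s.loc["halys", "ui_upper"]
        assert (s.loc["net_cost", "ui_lower"] <= det.net_cost
                <= s.loc["net_cost", "ui_upper"])
        assert (s["ui_lower"] <= s["mean"]).all() and (s["mean"] <= s["ui_upper"]).all()

    def test_ui_widens_with_input_cv(self, inputs):
        wide = dataclasses.replace(inputs, cost_items=default_cost_items(cv=0.3))
        narrow = dataclasses.replace(inputs, cost_items=default_cost_items(cv=0.05))
        rw = run_monte_carlo(wide, ScenarioConfig(), n=40, seed=5)
        rn = run_monte_carlo(narrow, ScenarioConfig(), n=40, seed=5)
        width = lambda r: (r.summary.loc["intervention_cost", "ui_upper"]
                           - r.summary.loc["intervention_cost", "ui_lower"])
        assert width(rw) > width(rn)

    def test_n_below_two_rejected(self, inputs):
        with pytest.raises(ValueError):
            run_monte_carlo(inputs, ScenarioConfig(), n=1)

    def test_results_files_written(self, inputs, tmp_path):
        res = run_monte_carlo(inputs, ScenarioConfig(), n=4, seed=1)
        write_results(res, tmp_path)
        assert (tmp_path / "results.json").exists()
        plane = pd.read_csv(tmp_path / "ce_plane.csv")
        assert list(plane.columns) == ["halys", "net_cost"] and len(plane) == 4


@pytest.fixture(scope="module")
def scenario_results(inputs):
    return run_scenarios(inputs, default_scenarios(), n=15, seed=13)


class TestScenarios:
    @pytest.fixture
    def results(self, scenario_results):
        return scenario_results

    def test_lower_discount_rate_raises_halys(self, results):
        assert (results["s4_discount_3pct"].summary.loc["halys", "mean"]
                > results["base"].summary.loc["halys", "mean"])

    def test_two_waves_cheaper_but_less_effective(self, results):
        base, s2 = results["base"].summary, results["s2_two_waves"].summary
        assert s2.loc["intervention_cost", "mean"] < base.loc["intervention_cost", "mean"]
        assert s2.loc["halys", "mean"] < base.loc["halys", "mean"]

    def test_truncated_horizon_reduces_halys(self, results):
        assert (results["s3_ten_year_horizon"].summary.loc["halys", "mean"]
                < results["base"].summary.loc["halys", "mean"])

    def test_wider_population_raises_halys(self, results):
        assert (results["s1_population_18plus"].summary.loc["halys", "mean"]
                > results["base"].summary.loc["halys", "mean"])

    def test_duplicate_names_rejected(self, inputs):
        with pytest.raises(ValueError):
            run_scenarios(inputs, [ScenarioConfig(), ScenarioConfig()], n=2)
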