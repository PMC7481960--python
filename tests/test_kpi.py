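import numpy as np
import pandas as pd
import pytest

from platchain import (
    REPORT_COST_UNIT,
    generate_scenarios,
    optimize,
    replay_policy,
    summarize,
    to_table,
)
from platchain.model import FirstStageDecisions
from platchain.simulate import ReplayResult

from conftest import make_config


def _replay_with_costs(costs_per_scenario, T=5):
    """Minimal ReplayResult carrying hand-set per-scenario total costs."""
    S = len(costs_per_scenario)
    zeros = np.zeros((2, T, S))
    comps = {
        n: zeros.copy()
        for n in (
            "fixed_operating", "fixed_shipping", "purchase",
            "holding", "shortage", "outdating",
        )
    }
    for s, c in enumerate(costs_per_scenario):
        comps["fixed_operating"][0, 0, s] = c
    units = {n: zeros.copy() for n in (
        "shortage", "shortage_total", "outdating", "holding", "purchased")}
    return ReplayResult(
        scenario_cost=np.asarray(costs_per_scenario, dtype=float),
        unit_kpis=units,
        cost_components=comps,
        probabilities=np.full(S, 1.0 / S),
    )


class TestSummarize:
    def test_hand_set_three_scenario_summary(self):
        cfg = make_config(horizon_days=5, n_scenarios=3)
        sc = generate_scenarios(cfg)
        rep = _replay_with_costs([50.0, 100.0, 150.0])
        report = summarize(rep, cfg, sc)
        assert report.avg_cost_per_day_per_scenario == pytest.approx(100 / 5)
        assert report.best_scenario_cost == pytest.approx(10)
        assert report.worst_scenario_cost == pytest.approx(30)
        # population std of {10, 20, 30}
        assert report.std_across_scenarios == pytest.approx(np.sqrt(200 / 3))

    def test_all_zero_policy_kpis(self):
        cfg = make_config(
            horizon_days=4, n_scenarios=1,
            demand=((0.0, 0.0),), supply=(0.0, 0.0),
            hospital_costs=dict(fixed_operating=5.0, fixed_shipping=113,
                                purchase=650, holding=130, shortage=3250,
                                outdating=650),
        )
        sc = generate_scenarios(cfg)
        fs = FirstStageDecisions(
            orders=np.zeros((1, 4), dtype=int),
            shipments=np.zeros((1, 4, 3), dtype=int),
            shipping_indicator=np.zeros((1, 4), dtype=int),
        )
        report = summarize(replay_policy(fs, sc, cfg), cfg, sc)
        assert (report.units.to_numpy() == 0).all()
        assert report.avg_cost_per_day_per_scenario == pytest.approx(5.0)
        assert report.std_across_scenarios == 0.0

    def test_summary_recomposes_solution_cost(self):
        cfg = make_config(horizon_days=6, n_scenarios=2, seed=8,
                          demand=((12.0, 3.0),), supply=(12.0, 3.0))
        sc = generate_scenarios(cfg)
        sol = optimize(cfg, sc, mip_rel_gap=0.0)
        report = summarize(sol, cfg, sc)
        assert report.avg_cost_per_day_per_scenario * 6 == pytest.approx(
            sol.objective_value
        )
        # entity costs add up to the overall average
        assert report.entity_cost.sum() == pytest.approx(
            report.avg_cost_per_day_per_scenario
        )

    def test_best_not_above_worst(self, small_base):
        cfg, sc, sol = small_base
        report = summarize(sol, cfg, sc)
        assert report.best_scenario_cost <= report.avg_cost_per_day_per_scenario
        assert report.avg_cost_per_day_per_scenario <= report.worst_scenario_cost

    def test_rejects_wrong_type(self, small_base):
        cfg, sc, _ = small_base
        with pytest.raises(TypeError):
            summarize({"not": "a solution"}, cfg, sc)


class TestToTable:
    def test_base_case_layout(self, small_base):
        cfg, sc, sol = small_base
        table = to_table(summarize(sol, cfg, sc), layout="base_case")
        assert list(table.columns)[:2] == ["hospital_1", "hospital_2"]
        assert "unit_shortage" in table.index
        assert "average_cost_per_day_per_scenario" in table.index

    def test_cost_table_scale_is_hundreds(self, small_base):
        cfg, sc, sol = small_base
        report = summarize(sol, cfg, sc)
        table = to_table({"base": report}, layout="cv_sweep")
        assert table.loc[0, "average_cost_per_day_per_scenario"] == pytest.approx(
            report.avg_cost_per_day_per_scenario / REPORT_COST_UNIT
        )

    def test_cost_settings_layout_per_entity(self, small_base):
        cfg, sc, sol = small_base
        report = summarize(sol, cfg, sc)
        table = to_table({"CSET1": report}, layout="cost_settings")
        assert set(table["entity"]) == {"hospital_1", "hospital_2", "blood_center"}

    def test_unknown_layout_rejected(self, small_base):
        cfg, sc, sol = small_base
        with pytest.raises(ValueError, match="layout"):
            to_table(summarize(sol, cfg, sc), layout="heatmap")

    def test_csv_roundtrip(self, small_base, tmp_path):
        cfg, sc, sol = small_base
        table = to_table(summarize(sol, cfg, sc), layout="base_case")
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        pd.testing.assert_frame_equal(back, table, check_exact=False)


class TestExports:
    def test_solution_csv_export(self, small_base, tmp_path):
        cfg, sc, sol = small_base
        written = sol.to_csv(tmp_path / "sol")
        assert "orders.csv" in written and "solution.json" in written
        orders = pd.read_csv(tmp_path / "sol" / "orders.csv")
        assert orders["value"].sum() == sol.first_stage.orders.sum()

    def test_daylog_csv_export(self, small_base, tmp_path):
        cfg, sc, sol = small_base
        from platchain import replay_policy

        rep = replay_policy(sol.first_stage, sc, cfg, keep_logs=True)
        rep.to_csv(tmp_path / "logs.csv")
        frame = pd.read_csv(tmp_path / "logs.csv")
        assert set(frame["entity"]) == {"hospital_1", "hospital_2", "blood_center"}
        shortages = frame[frame["field"] == "shortage"]
        # one shortage record per entity-day-scenario
        assert len(shortages) == 3 * 10 * 2
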