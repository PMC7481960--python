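"""Performance measures and cost summaries.

Unit KPIs (shortage, outdating, holding, purchased) are averaged over days
and scenarios per entity. Cost summaries aggregate each scenario's total
cost to a per-day figure and report the probability-weighted average, the
best and worst scenario, and the population standard deviation across
scenarios.

Cost summary *tables* are printed in hundreds of dollars — the package's
compact reporting convention; all in-memory figures are raw dollars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .model import Solution
from .scenarios import ScenarioSet
from .simulate import ReplayResult, replay_policy

__all__ = ["KPIReport", "summarize", "to_table", "REPORT_COST_UNIT"]

#: cost tables are emitted in this many dollars per printed unit
REPORT_COST_UNIT = 100.0

_UNIT_ROWS = ("shortage", "shortage_total", "outdating", "holding", "purchased")
_COMP_ROWS = (
    "fixed_operating",
    "fixed_shipping",
    "purchase",
    "holding",
    "shortage",
    "outdating",
)


@dataclass
class KPIReport:
    """Per-entity averages plus the overall cost summary.

    units            DataFrame, rows = unit KPIs (units/day), cols = entities
    cost_components  DataFrame, rows = cost components ($/day/scenario)
    entity_cost      Series, total $/day/scenario per entity
    avg_cost_per_day_per_scenario, best_scenario_cost, worst_scenario_cost,
    std_across_scenarios: floats, $/day
    """

    units: pd.DataFrame
    cost_components: pd.DataFrame
    entity_cost: pd.Series
    avg_cost_per_day_per_scenario: float
    best_scenario_cost: float
    worst_scenario_cost: float
    std_across_scenarios: float
    horizon_days: int
    n_scenarios: int

    def __post_init__(self):
        if not (
            self.best_scenario_cost
            <= self.avg_cost_per_day_per_scenario + 1e-9
            and self.avg_cost_per_day_per_scenario
            <= self.worst_scenario_cost + 1e-9
        ):
            raise ValueError("cost summary must satisfy best <= average <= worst")
        if (self.units.to_numpy() < -1e-9).any():
            raise ValueError("unit KPIs must be nonnegative")

    @property
    def entities(self) -> list[str]:
        return list(self.units.columns)

    def overall(self) -> dict[str, float]:
        return {
            "avg_cost_per_day_per_scenario": self.avg_cost_per_day_per_scenario,
            "best_scenario_cost": self.best_scenario_cost,
            "worst_scenario_cost": self.worst_scenario_cost,
            "std_across_scenarios": self.std_across_scenarios,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "units": self.units.to_dict(),
            "cost_components": self.cost_components.to_dict(),
            "entity_cost": self.entity_cost.to_dict(),
            "overall": self.overall(),
            "horizon_days": self.horizon_days,
            "n_scenarios": self.n_scenarios,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def summarize(
    solution_or_replay: Solution | ReplayResult,
    config: NetworkConfig,
    scenarios: ScenarioSet,
) -> KPIReport:
    """Aggregate a solved model or a replay into a :class:`KPIReport`.

    A :class:`~platchain.model.Solution` is first canonicalized by replaying
    its first-stage decisions through the event simulator, so the reported
    second-stage quantities are the event-consistent ones even if the
    solver returned a cost-equivalent non-canonical completion.
    """
    if isinstance(solution_or_replay, Solution):
        replay = replay_policy(solution_or_replay.first_stage, scenarios, config)
    elif isinstance(solution_or_replay, ReplayResult):
        replay = solution_or_replay
    else:
        raise TypeError(
            "expected a Solution or ReplayResult, got "
            f"{type(solution_or_replay).__name__}"
        )
    K = config.n_hospitals
    T = scenarios.horizon_days
    pb = np.asarray(replay.probabilities)
    if pb.shape != (scenarios.n_scenarios,):
        raise ValueError("replay and scenario set disagree on scenario count")
    names = [f"hospital_{h.id}" for h in config.hospitals] + ["blood_center"]

    units = pd.DataFrame(
        {
            name: {
                row: float((replay.unit_kpis[row][e] @ pb).sum() / T)
                for row in _UNIT_ROWS
            }
            for e, name in enumerate(names)
        }
    ).loc[list(_UNIT_ROWS), names]

    comps = pd.DataFrame(
        {
            name: {
                row: float((replay.cost_components[row][e] @ pb).sum() / T)
                for row in _COMP_ROWS
            }
            for e, name in enumerate(names)
        }
    ).loc[list(_COMP_ROWS), names]

    per_scenario_daily = replay.scenario_cost / T
    avg = float(pb @ per_scenario_daily)
    std = float(np.sqrt(pb @ (per_scenario_daily - avg) ** 2))
    return KPIReport(
        units=units,
        cost_components=comps,
        entity_cost=comps.sum(axis=0),
        avg_cost_per_day_per_scenario=avg,
        best_scenario_cost=float(per_scenario_daily.min()),
        worst_scenario_cost=float(per_scenario_daily.max()),
        std_across_scenarios=std,
        horizon_days=T,
        n_scenarios=scenarios.n_scenarios,
    )


def _base_case_table(report: KPIReport) -> pd.DataFrame:
    rows = {
        "unit_shortage": report.units.loc["shortage"],
        "unit_outdating": report.units.loc["outdating"],
        "unit_holding": report.units.loc["holding"],
        "unit_purchased": report.units.loc["purchased"],
        "fixed_cost": report.cost_components.loc["fixed_shipping"] / REPORT_COST_UNIT,
    }
    table = pd.DataFrame(rows).T
    overall = {
        "average_cost_per_day_per_scenario": report.avg_cost_per_day_per_scenario,
        "best": report.best_scenario_cost,
        "worst": report.worst_scenario_cost,
        "std": report.std_across_scenarios,
    }
    for key, value in overall.items():
        table.loc[key] = np.nan
        table.loc[key, table.columns[0]] = value / REPORT_COST_UNIT
    return table


def _comparison_table(
    reports: dict[str, KPIReport], per_entity: bool
) -> pd.DataFrame:
    rows = []
    for label, rep in reports.items():
        if per_entity:
            for entity in rep.entities:
                rows.append(
                    {
                        "setting": label,
                        "entity": entity,
                        "unit_shortage": rep.units.loc["shortage", entity],
                        "unit_outdating": rep.units.loc["outdating", entity],
                        "unit_holding": rep.units.loc["holding", entity],
                        "unit_purchased": rep.units.loc["purchased", entity],
                        "total_cost": rep.entity_cost[entity] / REPORT_COST_UNIT,
                    }
                )
        else:
            rows.append(
                {
                    "setting": label,
                    "average_cost_per_day_per_scenario": rep.avg_cost_per_day_per_scenario
                    / REPORT_COST_UNIT,
                    "best": rep.best_scenario_cost / REPORT_COST_UNIT,
                    "worst": rep.worst_scenario_cost / REPORT_COST_UNIT,
                    "std": rep.std_across_scenarios / REPORT_COST_UNIT,
                }
            )
    return pd.DataFrame(rows)


def to_table(
    report: KPIReport | dict[str, KPIReport],
    layout: str = "base_case",
) -> pd.DataFrame:
    """Render a report (or a labelled collection) in a published-table layout.

    ``base_case`` — one report: per-entity unit block plus the overall cost
    block. ``cv_sweep`` — collection: one row of overall cost measures per
    setting. ``cost_settings`` — collection: per-entity unit KPIs and total
    cost per setting. Cost figures are in hundreds of dollars.
    """
    if layout == "base_case":
        if not isinstance(report, KPIReport):
            raise TypeError("base_case layout expects a single KPIReport")
        return _base_case_table(report)
    if layout in ("cv_sweep", "cost_settings"):
        if isinstance(report, KPIReport):
            report = {"base": report}
        return _comparison_table(report, per_entity=layout == "cost_settings")
    raise ValueError(f"unknown layout: {layout!r}")
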