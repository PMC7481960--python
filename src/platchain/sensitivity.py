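"""Sensitivity experiments: demand/supply variability and cost settings.

Two experiment families:

* a sweep over the coefficient of variation (CV) of every demand and
  supply distribution — uncertainty is the knob, costs fixed;
* a grid of 17 cost settings — the base costs (CSET1), each of eight cost
  parameter families halved (CSET2-9), and each multiplied by 1.5
  (CSET10-17) — uncertainty fixed, prices the knob.

All settings within one sweep share scenario draws (common random numbers),
so differences in the resulting KPIs are attributable to the changed
parameter, not to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .config import CostParams, NetworkConfig
from .kpi import KPIReport, summarize, to_table
from .optimize import optimize
from .scenarios import apply_cv_setting, generate_scenarios

__all__ = [
    "CostSetting",
    "COST_SETTINGS",
    "build_cost_setting",
    "run_cv_sweep",
    "run_cost_settings",
]


@dataclass(frozen=True)
class CostSetting:
    """One row of the cost grid: a single scaled parameter family."""

    id: str
    target: str | None  # "bc" or "hospital"; None for the identity setting
    parameter: str | None
    factor: float

    def apply(self, base: CostParams) -> CostParams:
        if self.target is None:
            return base.model_copy(deep=True)
        if self.target == "bc":
            return base.model_copy(
                update={
                    "blood_center": base.blood_center.scaled(
                        self.parameter, self.factor
                    )
                }
            )
        return base.model_copy(
            update={
                "hospitals": [
                    h.scaled(self.parameter, self.factor) for h in base.hospitals
                ]
            }
        )


_FAMILIES = [
    ("bc", "holding"),
    ("bc", "shortage"),
    ("bc", "outdating"),
    ("hospital", "fixed_shipping"),
    ("hospital", "holding"),
    ("hospital", "purchase"),
    ("hospital", "shortage"),
    ("hospital", "outdating"),
]

COST_SETTINGS: dict[str, CostSetting] = {
    "CSET1": CostSetting(id="CSET1", target=None, parameter=None, factor=1.0)
}
for _i, (_t, _p) in enumerate(_FAMILIES):
    COST_SETTINGS[f"CSET{2 + _i}"] = CostSetting(
        id=f"CSET{2 + _i}", target=_t, parameter=_p, factor=0.5
    )
    COST_SETTINGS[f"CSET{10 + _i}"] = CostSetting(
        id=f"CSET{10 + _i}", target=_t, parameter=_p, factor=1.5
    )


def build_cost_setting(setting_id: str, base: CostParams) -> CostParams:
    """Return the base costs with the setting's parameter family rescaled."""
    try:
        setting = COST_SETTINGS[setting_id]
    except KeyError:
        raise ValueError(
            f"unknown cost setting {setting_id!r}; expected CSET1..CSET17"
        ) from None
    return setting.apply(base)


def _solve_and_summarize(config: NetworkConfig, seed: int, **solver_kw):
    scenarios = generate_scenarios(config, seed=seed)
    solution = optimize(config, scenarios, **solver_kw)
    return summarize(solution, config, scenarios), solution


def _pooled_report(reports: list[KPIReport]) -> KPIReport:
    """Average KPI reports across seeds (equal weight per seed)."""
    if len(reports) == 1:
        return reports[0]
    units = sum(r.units for r in reports) / len(reports)
    comps = sum(r.cost_components for r in reports) / len(reports)
    return KPIReport(
        units=units,
        cost_components=comps,
        entity_cost=comps.sum(axis=0),
        avg_cost_per_day_per_scenario=sum(
            r.avg_cost_per_day_per_scenario for r in reports
        )
        / len(reports),
        best_scenario_cost=min(r.best_scenario_cost for r in reports),
        worst_scenario_cost=max(r.worst_scenario_cost for r in reports),
        std_across_scenarios=sum(r.std_across_scenarios for r in reports)
        / len(reports),
        horizon_days=reports[0].horizon_days,
        n_scenarios=sum(r.n_scenarios for r in reports),
    )


def run_cv_sweep(
    config: NetworkConfig,
    cvs: Sequence[float],
    seeds: Iterable[int] = (1, 2, 3),
    *,
    mip_rel_gap: float = 1e-3,
    time_limit: float | None = None,
) -> tuple[pd.DataFrame, dict[float, KPIReport]]:
    """Solve the model for each CV level and tabulate overall cost measures.

    Returns the cost table (one row per CV, in hundreds of dollars) and the
    seed-pooled report per CV. Failures leave the affected cells out and
    are listed in the table's ``error`` column.
    """
    if not cvs:
        raise ValueError("cvs must be nonempty")
    seeds = list(seeds)
    reports: dict[float, KPIReport] = {}
    errors: dict[float, str] = {}
    for cv in cvs:
        cfg = apply_cv_setting(config, cv)
        per_seed = []
        try:
            for seed in seeds:
                rep, _ = _solve_and_summarize(
                    cfg, seed, mip_rel_gap=mip_rel_gap, time_limit=time_limit
                )
                per_seed.append(rep)
            reports[cv] = _pooled_report(per_seed)
        except RuntimeError as exc:  # solver failure: record, keep sweeping
            errors[cv] = str(exc)
    table = to_table(
        {f"CV = {cv:g}": rep for cv, rep in reports.items()}, layout="cv_sweep"
    )
    table.attrs["errors"] = errors  # partial table on solver failure
    if not reports:
        raise RuntimeError(f"every CV level failed: {errors}")
    return table, reports


def run_cost_settings(
    config: NetworkConfig,
    setting_ids: Sequence[str] = tuple(COST_SETTINGS),
    seeds: Iterable[int] = (1, 2, 3),
    *,
    mip_rel_gap: float = 1e-3,
    time_limit: float | None = None,
) -> tuple[pd.DataFrame, dict[str, KPIReport]]:
    """Re-solve the model under each cost setting on shared scenarios.

    The scenario seed(s) are identical across settings, isolating the cost
    effect. Returns a per-entity table (units/day and total cost per day
    per scenario in hundreds of dollars) plus the report per setting.
    """
    seeds = list(seeds)
    reports: dict[str, KPIReport] = {}
    errors: dict[str, str] = {}
    for sid in setting_ids:
        costs = build_cost_setting(sid, config.costs)
        cfg = config.with_costs(costs)
        try:
            per_seed = [
                _solve_and_summarize(
                    cfg, seed, mip_rel_gap=mip_rel_gap, time_limit=time_limit
                )[0]
                for seed in seeds
            ]
            reports[sid] = _pooled_report(per_seed)
        except RuntimeError as exc:
            errors[sid] = str(exc)
    table = to_table(reports, layout="cost_settings")
    table.attrs["errors"] = errors  # partial table on solver failure
    if not reports:
        raise RuntimeError(f"every cost setting failed: {errors}")
    return table, reports
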