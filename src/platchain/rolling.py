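"""Rolling-horizon driver.

In practice a planner does not freeze an entire horizon of orders: the
model is solved, only the first few days of the first-stage policy are
implemented, reality advances (one realized demand/supply path), and the
model is re-solved with updated inventories, in-transit deliveries, and
fresh scenario forecasts. The realized cost of the concatenated
implemented policy is what the planner actually pays.

The re-solve sees the world mid-stream through the warm-state hooks of
:func:`platchain.model.build_model`: current inventories become initial
inventories, supply already ordered but still in testing becomes the
center's early arrivals, and shipments still in transit become forced
hospital receipts.

First-stage shipments fix an age mix per delivery; on the realized path
the center's carried stock can fall short of the promised aged units, in
which case the residual is procured externally as fresh units (the same
recourse the model prices for its three-day shipments) — the repair is
deterministic and priced at the center's shortage rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .model import build_model, solve_model
from .scenarios import ScenarioSet, generate_scenarios
from .simulate import (
    InventoryState,
    blood_center_day_step,
    hospital_day_step,
    realized_supply_receipts,
)

__all__ = ["RollingResult", "rolling_horizon"]


@dataclass
class RollingResult:
    """Realized performance of the concatenated implemented policy."""

    realized_cost: float
    window_objectives: list[float]
    orders: np.ndarray  # (K, total_days) implemented orders
    shipments: np.ndarray  # (K, total_days, 3) implemented shipments
    realized_demand: np.ndarray  # (K, total_days)
    realized_supply: np.ndarray  # (total_days,)
    daily_cost: np.ndarray  # (total_days,)

    @property
    def total_days(self) -> int:
        return self.orders.shape[1]


def _window_seed(seed: int, w: int) -> int:
    return int(
        np.random.SeedSequence([seed, 2654435761, w]).generate_state(1)[0] % (2**31)
    )


def rolling_horizon(
    config: NetworkConfig,
    window_days: int,
    implement_days: int,
    n_windows: int,
    seed: int,
    *,
    mip_rel_gap: float = 1e-3,
    time_limit: float | None = None,
) -> RollingResult:
    """Iteratively solve, implement, advance; return the realized policy cost.

    ``seed`` drives the held-out realized path; each window's scenario
    forecast uses a distinct seed derived from it. The realized path is a
    single scenario drawn from the configured distributions.
    """
    if implement_days > window_days:
        raise ValueError("implement_days must not exceed window_days")
    if implement_days < 1 or n_windows < 1:
        raise ValueError("implement_days and n_windows must be positive")
    K = config.n_hospitals
    total = implement_days * n_windows
    lead = [h.lead_time_days for h in config.hospitals]
    ltbc = config.blood_center.lead_time_days

    real_cfg = config.model_copy(
        update={"horizon_days": total, "n_scenarios": 1, "seed": seed}
    )
    realized = generate_scenarios(real_cfg)
    demand = realized.demand[:, :, 0]
    supply = realized.supply[:, 0]
    rebc_real = realized_supply_receipts(real_cfg, supply)

    h_state = [
        InventoryState(dict(config.hospitals[k].initial_inventory)) for k in range(K)
    ]
    bc_state = InventoryState(dict(config.blood_center.initial_inventory))
    # (k, global arrival day) -> age map of units in transit
    in_transit: dict[tuple[int, int], dict[int, int]] = {}

    orders = np.zeros((K, total), dtype=np.int64)
    ships = np.zeros((K, total, 3), dtype=np.int64)
    daily_cost = np.zeros(total)
    objectives: list[float] = []

    for w in range(n_windows):
        base_day = w * implement_days  # 0-based global offset of the window
        win_cfg = config.model_copy(
            update={
                "horizon_days": window_days,
                "hospitals": [
                    h.model_copy(
                        update={
                            "initial_inventory": {
                                l: h_state[k].get(l) for l in (1, 2) if h_state[k].get(l)
                            }
                        }
                    )
                    for k, h in enumerate(config.hospitals)
                ],
                "blood_center": config.blood_center.model_copy(
                    update={
                        "initial_inventory": {
                            l: bc_state.get(l) for l in (1, 2) if bc_state.get(l)
                        }
                    }
                ),
            }
        )
        win_sc = generate_scenarios(win_cfg, seed=_window_seed(seed, w))
        center_override: dict[int, int] = {}
        for d in range(1, min(ltbc, window_days) + 1):
            g = base_day + d  # 1-based global day
            if g <= total:
                center_override[d] = int(rebc_real[g])
            else:  # beyond the realized path: fall back on the mean
                center_override[d] = round(config.blood_center.supply.mean)
        hosp_arrivals = {}
        for (k, g_day), ages in in_transit.items():
            d = g_day - base_day
            if 1 <= d <= window_days:
                arr = np.zeros(3)
                for l, u in ages.items():
                    arr[l - 1] = u
                hosp_arrivals[(k, d)] = arr
        model = build_model(
            win_cfg,
            win_sc,
            strict_fifo="stock",
            center_arrivals_override=center_override,
            hospital_arrivals=hosp_arrivals,
        )
        solution = solve_model(model, mip_rel_gap=mip_rel_gap, time_limit=time_limit)
        objectives.append(solution.objective_value)

        # implement the window's first days on the realized path
        for d in range(implement_days):
            g = base_day + d  # 0-based global day
            # promised age mix, repaired against realized stock
            ship_day = [
                {l: int(solution.first_stage.shipments[k, d, l - 1]) for l in (1, 2, 3)}
                for k in range(K)
            ]
            for l in (1, 2):
                avail = bc_state.get(l)
                for k in range(K):
                    over = max(0, ship_day[k][l] - avail)
                    take = ship_day[k][l] - over
                    avail -= take
                    if over:
                        ship_day[k][3] += over  # fresh external substitute
                        ship_day[k][l] -= over
            # queue deliveries; zero lead time lands the same day
            for k in range(K):
                arrive = g + 1 + lead[k]
                aged = {
                    l - lead[k]: u
                    for l, u in ship_day[k].items()
                    if u and l - lead[k] >= 1
                }
                if aged and arrive <= total:
                    prev = in_transit.setdefault((k, arrive), {})
                    for l, u in aged.items():
                        prev[l] = prev.get(l, 0) + u
            emergencies = [0] * K
            h_logs = []
            for k in range(K):
                receipts = in_transit.pop((k, g + 1), {})
                h_state[k], log = hospital_day_step(
                    h_state[k],
                    receipts,
                    int(demand[k, g]),
                    config.costs.hospitals[k],
                    order_placed=int(solution.first_stage.orders[k, d]),
                    entity=f"hospital_{config.hospitals[k].id}",
                    day=g + 1,
                )
                emergencies[k] = log.shortage
                h_logs.append(log)
            bc_state, bc_log, shipped = blood_center_day_step(
                bc_state,
                int(rebc_real[g + 1]),
                [sum(s.values()) for s in ship_day],
                emergencies,
                lead,
                config.costs.blood_center,
                shipments_by_hospital=ship_day,
                day=g + 1,
            )
            orders[:, g] = solution.first_stage.orders[:, d]
            for k in range(K):
                for l in (1, 2, 3):
                    ships[k, g, l - 1] = shipped[k].get(l, 0)
            daily_cost[g] = sum(log.total_cost for log in h_logs) + bc_log.total_cost

    return RollingResult(
        realized_cost=float(daily_cost.sum()),
        window_objectives=objectives,
        orders=orders,
        shipments=ships,
        realized_demand=demand,
        realized_supply=supply,
        daily_cost=daily_cost,
    )
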