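"""Deterministic event-replay of the daily platelet flows.

This module re-executes, day by day, the operational sequence that the
optimization model encodes algebraically:

hospital day
    open with carried stock (ages 1-2) -> receive shipments (ages 1-3) ->
    observe demand -> issue FIFO (oldest first) -> unmet demand becomes a
    same-day emergency order on the blood center -> age-1 leftovers expire,
    the rest age one day overnight.

blood-center day
    open with carried stock (ages 1-2) -> receive tested units from the
    component labs (age 3) -> ship against the hospitals' regular orders
    (only ages that survive the transit lead time) -> serve the hospitals'
    emergency orders from what is left, oldest first -> residual regular
    shipments are procured externally (arriving as fresh 3-day units),
    residual emergency demand is procured externally as well -> expire and
    age.

Because every step is a closed-form cascade, replaying a solved model's
first-stage decisions reproduces its objective value exactly; the replay is
the package's independent cost oracle and also evaluates hand-written
policies the optimizer never saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .scenarios import ScenarioSet

__all__ = [
    "InventoryState",
    "DayLog",
    "fifo_issue",
    "hospital_day_step",
    "blood_center_day_step",
    "replay_policy",
    "ReplayResult",
    "realized_supply_receipts",
]

AGES = (1, 2, 3)


def _as_age_map(mapping) -> dict[int, int]:
    return {l: int(mapping.get(l, 0)) for l in AGES}


@dataclass
class InventoryState:
    """Units on hand keyed by remaining shelf life (1, 2 or 3 days)."""

    units_by_age: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.units_by_age = {
            l: int(u) for l, u in self.units_by_age.items() if u
        }
        if any(l not in AGES for l in self.units_by_age):
            raise ValueError("shelf life must be 1, 2 or 3 days")
        if any(u < 0 for u in self.units_by_age.values()):
            raise ValueError("inventory must be nonnegative")

    def get(self, age: int) -> int:
        return self.units_by_age.get(age, 0)

    def total(self) -> int:
        return sum(self.units_by_age.values())


@dataclass
class DayLog:
    """One entity-day: flows by age plus the day's cost breakdown."""

    entity: str
    day: int
    scenario: int
    opening: dict[int, int]
    received: dict[int, int]
    issued: dict[int, int]
    shortage: int
    expired: int
    closing: dict[int, int]
    costs: dict[str, float]
    # blood-center only: split of the day's shortage and emergency issues
    shortage_regular: int = 0
    shortage_emergency: int = 0
    shortage_by_hospital: list[int] = field(default_factory=list)
    emergency_issued: dict[int, int] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))


def fifo_issue(
    inventory: InventoryState | dict,
    receipts_by_age: dict,
    demand: int,
) -> tuple[dict[int, int], dict[int, int], int]:
    """Issue ``demand`` units oldest-first from stock plus receipts.

    Returns ``(issued_by_age, leftover_by_age, unmet)``. Units with one day
    of shelf life go first, then two, then three; leftovers keep their age.
    """
    if demand < 0:
        raise ValueError("demand must be nonnegative")
    stock = inventory.units_by_age if isinstance(inventory, InventoryState) else inventory
    pool = _as_age_map(stock)
    for l, u in _as_age_map(receipts_by_age).items():
        pool[l] += u
    issued: dict[int, int] = {}
    leftover: dict[int, int] = {}
    remaining = int(demand)
    for l in AGES:
        take = min(pool[l], remaining)
        if take:
            issued[l] = take
        remaining -= take
        if pool[l] - take:
            leftover[l] = pool[l] - take
    return issued, leftover, remaining


def hospital_day_step(
    state: InventoryState,
    receipts_by_age: dict,
    demand: int,
    costs,
    order_placed: int = 0,
    *,
    entity: str = "hospital",
    day: int = 0,
    scenario: int = 0,
) -> tuple[InventoryState, DayLog]:
    """Run one hospital day and price it.

    ``costs`` is an :class:`~platchain.config.EntityCosts`. The shortage
    reported in the log is the day's unmet demand, covered same-day by an
    emergency order at the ``shortage`` (emergency-procurement) price.
    Holding is charged on the opening inventory; the purchase price applies
    to ``order_placed`` (the day's regular order).
    """
    opening = {l: state.get(l) for l in (1, 2)}
    if state.get(3):
        raise ValueError("carried stock cannot have three days of shelf life")
    issued, leftover, unmet = fifo_issue(state, receipts_by_age, demand)
    expired = leftover.get(1, 0)
    nxt = InventoryState({1: leftover.get(2, 0), 2: leftover.get(3, 0)})
    received = _as_age_map(receipts_by_age)
    day_costs = {
        "fixed_operating": costs.fixed_operating,
        "fixed_shipping": costs.fixed_shipping if sum(received.values()) > 0 else 0.0,
        "purchase": costs.purchase * order_placed,
        "holding": costs.holding * sum(opening.values()),
        "shortage": costs.shortage * unmet,
        "outdating": costs.outdating * expired,
    }
    log = DayLog(
        entity=entity,
        day=day,
        scenario=scenario,
        opening=opening,
        received=received,
        issued=issued,
        shortage=unmet,
        expired=expired,
        closing={l: nxt.get(l) for l in (1, 2)},
        costs=day_costs,
    )
    return nxt, log


def _greedy_regular_allocation(
    pool: dict[int, int],
    orders: list[int],
    lead_times: list[int],
) -> list[dict[int, int]]:
    """Age-ascending allocation of regular orders, oldest usable stock first.

    A unit shipped at age ``l`` to a hospital with lead time ``LT`` arrives
    with ``l - LT`` days left, so only ages ``l > LT`` may ship.
    """
    remaining = [int(q) for q in orders]
    ship: list[dict[int, int]] = [dict() for _ in orders]
    for l in AGES:
        for k in range(len(orders)):
            if l <= lead_times[k]:
                continue
            take = min(pool[l], remaining[k])
            if take:
                ship[k][l] = ship[k].get(l, 0) + take
                pool[l] -= take
                remaining[k] -= take
    return ship


def _pro_rata(quantity: int, weights: list[int]) -> list[int]:
    """Split ``quantity`` proportionally to ``weights``, largest remainder."""
    total = sum(weights)
    if total == 0 or quantity == 0:
        return [0] * len(weights)
    quantity = min(quantity, total)
    raw = [quantity * w / total for w in weights]
    base = [int(np.floor(r)) for r in raw]
    order = sorted(
        range(len(weights)), key=lambda i: (raw[i] - base[i]), reverse=True
    )
    deficit = quantity - sum(base)
    while deficit > 0:
        for i in order:  # one unit per pass, largest remainders first
            if deficit and base[i] < weights[i]:
                base[i] += 1
                deficit -= 1
    return base


def blood_center_day_step(
    state: InventoryState,
    component_lab_receipts: int,
    regular_orders_by_hospital: list[int],
    emergency_orders_by_hospital: list[int],
    lead_times: list[int],
    costs,
    *,
    shipments_by_hospital: list[dict[int, int]] | None = None,
    price_emergency_shortage: bool = False,
    day: int = 0,
    scenario: int = 0,
) -> tuple[InventoryState, DayLog, list[dict[int, int]]]:
    """Run one blood-center day.

    With ``shipments_by_hospital`` given (audit mode) the stated regular
    shipments are executed verbatim; otherwise a greedy age-ascending
    allocation is computed (policy mode). Regular shipments that exceed the
    day's fresh arrivals are procured externally and still reach the
    hospital as 3-day units. Emergency orders are served oldest-first from
    the leftover stock, pro rata across hospitals when it is scarce; the
    residual is procured externally.

    The center's shortage cost prices the external procurement triggered by
    regular orders; set ``price_emergency_shortage`` to also price the
    emergency residual (the hospitals already pay the emergency-procurement
    price for those units).
    """
    opening = {l: state.get(l) for l in (1, 2)}
    if state.get(3):
        raise ValueError("carried stock cannot have three days of shelf life")
    rebc = int(component_lab_receipts)
    pool = {1: opening[1], 2: opening[2], 3: rebc}
    K = len(regular_orders_by_hospital)
    if len(lead_times) != K or len(emergency_orders_by_hospital) != K:
        raise ValueError("orders and lead times must align per hospital")

    if shipments_by_hospital is None:
        ship = _greedy_regular_allocation(pool, regular_orders_by_hospital, lead_times)
        shrbc_by_hospital = [
            int(regular_orders_by_hospital[k]) - sum(ship[k].values())
            for k in range(K)
        ]
        # externally procured units arrive fresh (3-day shelf life)
        for k in range(K):
            if shrbc_by_hospital[k]:
                ship[k][3] = ship[k].get(3, 0) + shrbc_by_hospital[k]
    else:
        ship = [_as_age_map(s) for s in shipments_by_hospital]
        for k in range(K):
            for l in AGES:
                if ship[k][l] and l <= lead_times[k]:
                    raise ValueError(
                        f"hospital {k}: age-{l} shipment cannot survive a "
                        f"{lead_times[k]}-day lead time"
                    )
            if sum(ship[k].values()) != int(regular_orders_by_hospital[k]):
                raise ValueError(
                    f"hospital {k}: shipments must cover the regular order"
                )
        for l in (1, 2):
            shipped_l = sum(s[l] for s in ship)
            if shipped_l > pool[l]:
                raise ValueError(
                    f"day {day}: age-{l} shipments exceed on-hand stock"
                )
            pool[l] -= shipped_l
        shipped_3 = sum(s[3] for s in ship)
        hp3_total = min(shipped_3, pool[3])
        shrbc_total = shipped_3 - hp3_total
        pool[3] -= hp3_total
        shrbc_by_hospital = _pro_rata(shrbc_total, [s[3] for s in ship])

    shrbc_total = sum(shrbc_by_hospital)

    # emergency cascade on leftover stock, oldest first
    emergency_total = int(sum(emergency_orders_by_hospital))
    remaining = emergency_total
    leftover: dict[int, int] = {}
    emergency_issued: dict[int, int] = {}
    for l in AGES:
        take = min(pool[l], remaining)
        if take:
            emergency_issued[l] = take
        remaining -= take
        leftover[l] = pool[l] - take
    shebc = remaining
    expired = leftover[1]
    nxt = InventoryState({1: leftover[2], 2: leftover[3]})

    priced_shortage = shrbc_total + (shebc if price_emergency_shortage else 0)
    day_costs = {
        "fixed_operating": costs.fixed_operating,
        "fixed_shipping": costs.fixed_shipping if rebc > 0 else 0.0,
        "purchase": 0.0,  # processing/testing is recovered from the hospitals
        "holding": costs.holding * sum(opening.values()),
        "shortage": costs.shortage * priced_shortage,
        "outdating": costs.outdating * expired,
    }
    issued = {
        l: sum(s.get(l, 0) for s in ship) - (shrbc_total if l == 3 else 0)
        for l in AGES
    }
    log = DayLog(
        entity="blood_center",
        day=day,
        scenario=scenario,
        opening=opening,
        received={3: rebc},
        issued={l: u for l, u in issued.items() if u},
        shortage=shrbc_total + shebc,
        expired=expired,
        closing={l: nxt.get(l) for l in (1, 2)},
        costs=day_costs,
        shortage_regular=shrbc_total,
        shortage_emergency=shebc,
        shortage_by_hospital=list(shrbc_by_hospital),
        emergency_issued=emergency_issued,
    )
    return nxt, log, ship


def realized_supply_receipts(config: NetworkConfig, supply_path: np.ndarray) -> np.ndarray:
    """Component-lab arrivals REBC[t] implied by a supply path ORBC.

    The center's procurement equals the day's donor supply, accumulated onto
    review days when the review period exceeds one day, and arrives after
    the testing lead time. Days before the first in-horizon arrival are
    filled by pre-horizon procurement at the supply mean when the
    configuration primes the pipeline, and receive nothing on a cold start.
    """
    T = len(supply_path)
    lt = config.blood_center.lead_time_days
    rp = config.blood_center.review_period_days
    orbc = np.zeros(T + 1, dtype=np.int64)
    carry = 0
    for t in range(1, T + 1):
        carry += int(supply_path[t - 1])
        if t % rp == 0:
            orbc[t] = carry
            carry = 0
    rebc = np.zeros(T + 1, dtype=np.int64)
    for t in range(lt + 1, T + 1):
        rebc[t] = orbc[t - lt]
    if config.supply_pipeline == "primed":
        for t in range(1, min(lt, T) + 1):
            rebc[t] = round(config.blood_center.supply.mean)
    return rebc


@dataclass
class ReplayResult:
    """Per-scenario costs and KPI series from a replay.

    ``unit_kpis[name]`` has shape (K+1, T, S) with hospitals first and the
    blood center last; ``cost_components[name]`` likewise. ``scenario_cost``
    has shape (S,). The center's ``shortage`` row counts the external
    procurement for regular orders (the priced quantity);
    ``shortage_total`` adds the emergency residual.
    """

    scenario_cost: np.ndarray
    unit_kpis: dict[str, np.ndarray]
    cost_components: dict[str, np.ndarray]
    probabilities: np.ndarray
    logs: list[DayLog] | None = None

    @property
    def expected_cost(self) -> float:
        return float(self.probabilities @ self.scenario_cost)

    def logs_to_frame(self):
        """Long-format day-log table (entity, day, scenario, field, value).

        Requires the replay to have been run with ``keep_logs=True``.
        """
        import pandas as pd

        if self.logs is None:
            raise ValueError("replay was run without keep_logs=True")
        rows = []
        for log in self.logs:
            base = {"entity": log.entity, "day": log.day, "scenario": log.scenario}
            for field_name, mapping in (
                ("opening", log.opening),
                ("received", log.received),
                ("issued", log.issued),
                ("closing", log.closing),
            ):
                for age, units in mapping.items():
                    rows.append(base | {"field": f"{field_name}_age{age}", "value": units})
            rows.append(base | {"field": "shortage", "value": log.shortage})
            rows.append(base | {"field": "expired", "value": log.expired})
            for comp, value in log.costs.items():
                rows.append(base | {"field": f"cost_{comp}", "value": value})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.logs_to_frame().to_csv(path, index=False)


def replay_policy(
    first_stage,
    scenarios: ScenarioSet,
    config: NetworkConfig,
    *,
    mode: str = "audit",
    price_emergency_shortage: bool = False,
    keep_logs: bool = False,
    repair_shipments: bool = False,
) -> ReplayResult:
    """Replay first-stage decisions across every scenario and price them.

    ``first_stage`` provides ``orders`` of shape (K, T) and, in audit mode,
    ``shipments`` of shape (K, T, 3) (shipment day, shipped age); arrival at
    the hospital is on day ``t + LTHP_k`` at age ``l - LTHP_k``. In
    ``mode="policy"`` the blood center allocates shipments itself, greedily
    per scenario.

    ``repair_shipments`` substitutes fresh externally procured units for
    aged shipments the day's stock cannot cover (the rolling-horizon
    driver's recourse when a plan meets a path outside its scenario set);
    without it such a plan is rejected as infeasible.
    """
    if mode not in ("audit", "policy"):
        raise ValueError("mode must be 'audit' or 'policy'")
    K, T, S = scenarios.demand.shape
    orders = np.asarray(first_stage.orders, dtype=np.int64)
    if orders.shape != (K, T):
        raise ValueError(f"orders must have shape {(K, T)}")
    shipments = None
    if mode == "audit":
        shipments = np.asarray(first_stage.shipments, dtype=np.int64)
        if shipments.shape != (K, T, 3):
            raise ValueError(f"shipments must have shape {(K, T, 3)}")

    lead_times = [h.lead_time_days for h in config.hospitals]
    names = [f"hospital_{h.id}" for h in config.hospitals] + ["blood_center"]
    kpi_names = ("shortage", "shortage_total", "outdating", "holding", "purchased")
    comp_names = (
        "fixed_operating", "fixed_shipping", "purchase",
        "holding", "shortage", "outdating",
    )
    unit_kpis = {n: np.zeros((K + 1, T, S)) for n in kpi_names}
    comps = {n: np.zeros((K + 1, T, S)) for n in comp_names}
    logs: list[DayLog] = []

    for s in range(S):
        rebc = realized_supply_receipts(config, scenarios.supply[:, s])
        h_state = [
            InventoryState(dict(config.hospitals[k].initial_inventory))
            for k in range(K)
        ]
        bc_state = InventoryState(dict(config.blood_center.initial_inventory))
        # shipments en route: arrivals[k][t] = age map reaching hospital k on day t
        arrivals: list[dict[int, dict[int, int]]] = [dict() for _ in range(K)]
        for t in range(1, T + 1):
            day_ship_requests = [int(orders[k, t - 1]) for k in range(K)]
            # regular shipments are fixed before demand resolves: given in
            # audit mode, allocated greedily from today's stock otherwise
            if mode == "audit":
                ship = [
                    {l: int(shipments[k, t - 1, l - 1]) for l in AGES}
                    for k in range(K)
                ]
                if repair_shipments:
                    for l in (1, 2):
                        avail = bc_state.get(l)
                        for k in range(K):
                            over = max(0, ship[k][l] - avail)
                            avail -= ship[k][l] - over
                            if over:
                                ship[k][3] += over  # fresh external substitute
                                ship[k][l] -= over
            else:
                pool = {1: bc_state.get(1), 2: bc_state.get(2), 3: int(rebc[t])}
                ship = _greedy_regular_allocation(
                    pool, day_ship_requests, lead_times
                )
                for k in range(K):  # residual is procured externally, fresh
                    residual = day_ship_requests[k] - sum(ship[k].values())
                    if residual:
                        ship[k][3] = ship[k].get(3, 0) + residual
            # queue for arrival after the lead time; zero lead time lands today
            for k in range(K):
                total_shipped = sum(ship[k].values())
                if not total_shipped:
                    continue
                arrive_day = t + lead_times[k]
                if arrive_day > T:
                    if repair_shipments:
                        continue  # paid for, but lands beyond the evaluation window
                    raise ValueError(
                        f"day {t}: shipment to hospital {k} arrives after the horizon"
                    )
                aged = {
                    l - lead_times[k]: u
                    for l, u in ship[k].items()
                    if u and l - lead_times[k] >= 1
                }
                if sum(aged.values()) != total_shipped:
                    raise ValueError(
                        f"day {t}: shipment to hospital {k} expires in transit"
                    )
                arrivals[k][arrive_day] = aged

            # hospitals: receive, serve demand, record emergencies
            emergencies = [0] * K
            h_logs = []
            for k in range(K):
                receipts = arrivals[k].pop(t, {})
                h_state[k], log = hospital_day_step(
                    h_state[k],
                    receipts,
                    int(scenarios.demand[k, t - 1, s]),
                    config.costs.hospitals[k],
                    order_placed=int(orders[k, t - 1]),
                    entity=names[k],
                    day=t,
                    scenario=s,
                )
                emergencies[k] = log.shortage
                h_logs.append(log)

            bc_state, bc_log, ship = blood_center_day_step(
                bc_state,
                int(rebc[t]),
                day_ship_requests,
                emergencies,
                lead_times,
                config.costs.blood_center,
                shipments_by_hospital=ship,
                price_emergency_shortage=price_emergency_shortage,
                day=t,
                scenario=s,
            )

            for e, log in enumerate(h_logs + [bc_log]):
                for n in comp_names:
                    comps[n][e, t - 1, s] = log.costs[n]
                unit_kpis["outdating"][e, t - 1, s] = log.expired
                unit_kpis["holding"][e, t - 1, s] = sum(log.opening.values())
                if e < K:
                    unit_kpis["shortage"][e, t - 1, s] = log.shortage
                    unit_kpis["shortage_total"][e, t - 1, s] = log.shortage
                    unit_kpis["purchased"][e, t - 1, s] = orders[e, t - 1]
                else:
                    unit_kpis["shortage"][e, t - 1, s] = log.shortage_regular
                    unit_kpis["shortage_total"][e, t - 1, s] = log.shortage
                    unit_kpis["purchased"][e, t - 1, s] = scenarios.supply[t - 1, s]
            if keep_logs:
                logs.extend(h_logs)
                logs.append(bc_log)

    scenario_cost = sum(comps[n].sum(axis=(0, 1)) for n in comp_names)
    return ReplayResult(
        scenario_cost=np.asarray(scenario_cost, dtype=float),
        unit_kpis=unit_kpis,
        cost_components=comps,
        probabilities=scenarios.probabilities,
        logs=logs if keep_logs else None,
    )
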