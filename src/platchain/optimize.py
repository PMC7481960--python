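"""High-level solve workflow: optimize, canonicalize, certify.

The exact event-consistent model (``strict_fifo="full"``) carries one
indicator binary per cascade stage, day and scenario, which is expensive
at experiment scale. This module implements the production path:

1. solve the ``"stock"`` model — hoarding-prevention indicators only;
2. harden the shipment plan: clip any committed aged shipment to the
   stock available in the worst scenario (gap-terminated solves can leave
   a physically undeliverable aged unit in the plan) — a deterministic,
   scenario-invariant repair that touches only undeliverable units;
3. replay the hardened first stage through the event simulator, which
   yields the canonical (event-consistent) second stage and its exact
   expected cost;
4. certify: the solver's dual bound limits every policy from below and
   the replayed cost is attained, so the returned policy is proven within
   ``(replay - bound) / replay`` of optimal (observed well inside the
   solver's own gap tolerance on base-family instances).

The returned :class:`~platchain.model.Solution` carries the replayed cost
as its objective, the canonical second stage, and the lower bound.
"""

from __future__ import annotations

import numpy as np

from .config import NetworkConfig
from .model import (
    FirstStageDecisions,
    SecondStageDecisions,
    Solution,
    build_model,
    solve_model,
)
from .scenarios import ScenarioSet
from .simulate import (
    InventoryState,
    ReplayResult,
    blood_center_day_step,
    hospital_day_step,
    realized_supply_receipts,
    replay_policy,
)

__all__ = ["canonical_second_stage", "harden_shipments", "optimize"]


def harden_shipments(
    first_stage: FirstStageDecisions,
    config: NetworkConfig,
    scenarios: ScenarioSet,
) -> FirstStageDecisions:
    """Make a shipment plan executable in every scenario.

    A gap-terminated solve can commit an aged shipment against stock the
    canonical event dynamics do not actually hold in some scenario. This
    pass walks all scenarios forward in lockstep: each day, each aged
    shipment is clipped to the stock available in the *worst* scenario and
    the shortfall is moved to fresh units (age 3 is always deliverable —
    external procurement backs it). The repaired plan stays scenario
    invariant and changes only units that were physically undeliverable.
    """
    K, T, S = scenarios.demand.shape
    lead = [h.lead_time_days for h in config.hospitals]
    ships = first_stage.shipments.copy()
    orders = first_stage.orders

    rebc = np.zeros((T + 1, S), dtype=np.int64)
    for s in range(S):
        rebc[:, s] = realized_supply_receipts(config, scenarios.supply[:, s])
    h_state = [
        [InventoryState(dict(config.hospitals[k].initial_inventory)) for k in range(K)]
        for _ in range(S)
    ]
    bc_state = [
        InventoryState(dict(config.blood_center.initial_inventory)) for _ in range(S)
    ]
    arrivals: list[list[dict[int, dict[int, int]]]] = [
        [dict() for _ in range(K)] for _ in range(S)
    ]
    for t in range(1, T + 1):
        # clip aged shipments to what every scenario can actually supply
        for l in (1, 2):
            avail = min(bc_state[s].get(l) for s in range(S))
            for k in range(K):
                take = min(int(ships[k, t - 1, l - 1]), avail)
                over = int(ships[k, t - 1, l - 1]) - take
                avail -= take
                if over:
                    ships[k, t - 1, l - 1] -= over
                    ships[k, t - 1, 2] += over
        ship_maps = [
            {l: int(ships[k, t - 1, l - 1]) for l in (1, 2, 3)} for k in range(K)
        ]
        for s in range(S):
            for k in range(K):
                aged = {
                    l - lead[k]: u
                    for l, u in ship_maps[k].items()
                    if u and l - lead[k] >= 1
                }
                if aged and t + lead[k] <= T:
                    arrivals[s][k][t + lead[k]] = aged
            emergencies = [0] * K
            for k in range(K):
                h_state[s][k], log = hospital_day_step(
                    h_state[s][k],
                    arrivals[s][k].pop(t, {}),
                    int(scenarios.demand[k, t - 1, s]),
                    config.costs.hospitals[k],
                )
                emergencies[k] = log.shortage
            bc_state[s], _, _ = blood_center_day_step(
                bc_state[s],
                int(rebc[t, s]),
                [sum(m.values()) for m in ship_maps],
                emergencies,
                lead,
                config.costs.blood_center,
                shipments_by_hospital=ship_maps,
                day=t,
            )
    if np.array_equal(ships, first_stage.shipments):
        return first_stage
    return FirstStageDecisions(
        orders=orders,
        shipments=ships,
        shipping_indicator=(ships.sum(axis=2) > 0).astype(np.int64),
    )


def canonical_second_stage(
    first_stage: FirstStageDecisions,
    config: NetworkConfig,
    scenarios: ScenarioSet,
) -> tuple[SecondStageDecisions, ReplayResult]:
    """Event-consistent second stage implied by first-stage decisions."""
    replay = replay_policy(first_stage, scenarios, config, keep_logs=True)
    K, T, S = scenarios.demand.shape
    rd = np.zeros((K, T, 3, S))
    ly = np.zeros((K, T, 3, S))
    lfr = np.zeros((T, 3, S))
    lfe = np.zeros((T, 3, S))
    rsh = np.zeros((T, 3, S))
    shr = np.zeros((K, T, S))
    names = {f"hospital_{h.id}": k for k, h in enumerate(config.hospitals)}
    for log in replay.logs:
        t0, s = log.day - 1, log.scenario
        if log.entity in names:
            k = names[log.entity]
            demand = int(scenarios.demand[k, t0, s])
            rd[k, t0, 0, s] = demand - log.issued.get(1, 0)
            rd[k, t0, 1, s] = rd[k, t0, 0, s] - log.issued.get(2, 0)
            rd[k, t0, 2, s] = rd[k, t0, 1, s] - log.issued.get(3, 0)
            ly[k, t0, 0, s] = log.expired
            ly[k, t0, 1, s] = log.closing.get(1, 0)
            ly[k, t0, 2, s] = log.closing.get(2, 0)
        else:
            lfr[t0, 0, s] = log.opening.get(1, 0) - log.issued.get(1, 0)
            lfr[t0, 1, s] = log.opening.get(2, 0) - log.issued.get(2, 0)
            lfr[t0, 2, s] = log.received.get(3, 0) - log.issued.get(3, 0)
            em = log.emergency_issued
            served = [em.get(1, 0), em.get(2, 0), em.get(3, 0)]
            total_em = sum(served) + log.shortage_emergency
            rsh[t0, 0, s] = total_em - served[0]
            rsh[t0, 1, s] = rsh[t0, 0, s] - served[1]
            rsh[t0, 2, s] = rsh[t0, 1, s] - served[2]
            for l in range(3):
                lfe[t0, l, s] = lfr[t0, l, s] - served[l]
            if log.shortage_by_hospital:
                shr[:, t0, s] = log.shortage_by_hospital
    second = SecondStageDecisions(
        remaining_demand=rd,
        leftover=ly,
        center_left_regular=lfr,
        center_left_emergency=lfe,
        center_remaining_emergency=rsh,
        center_external_regular=shr,
    )
    return second, replay


def optimize(
    config: NetworkConfig,
    scenarios: ScenarioSet,
    *,
    mip_rel_gap: float = 1e-3,
    time_limit: float | None = None,
    strict_fifo: bool | str = "stock",
    price_emergency_shortage: bool = False,
) -> Solution:
    """Solve, canonicalize and certify in one call.

    ``objective_value`` of the result is the exact expected cost of the
    returned first-stage policy under the event rules; ``lower_bound`` is
    the solver's certificate that no policy beats it by more than
    ``objective_value - lower_bound``.
    """
    model = build_model(
        config,
        scenarios,
        strict_fifo=strict_fifo,
        price_emergency_shortage=price_emergency_shortage,
    )
    raw = solve_model(model, mip_rel_gap=mip_rel_gap, time_limit=time_limit)
    hardened = harden_shipments(raw.first_stage, config, scenarios)
    second, replay = canonical_second_stage(hardened, config, scenarios)
    # recompute the indicator from actual deliveries (a solver may leave a
    # costless spare indicator at 1 on a zero-order day)
    first = FirstStageDecisions(
        orders=hardened.orders,
        shipments=hardened.shipments,
        shipping_indicator=(hardened.shipments.sum(axis=2) > 0).astype(np.int64),
    )
    # the solver's dual bound limits any policy from below; the replay
    # cost is attained, hence an upper bound
    return Solution(
        first_stage=first,
        second_stage=second,
        objective_value=float(replay.expected_cost),
        status=raw.status,
        mip_gap=raw.mip_gap,
        solver_message=raw.solver_message,
        lower_bound=float(min(raw.lower_bound, replay.expected_cost)),
    )
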