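"""Post-hoc validation of solved instances.

The optimizer is trusted but verified: every solved instance is checked
against the identities the formulation is supposed to guarantee —
FIFO complementarity at each cascade stage, unit conservation at every
entity-day, overnight aging, the shortage-accounting identity at the blood
center, and scenario-invariance (nonanticipativity) of the first stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .model import Solution
from .scenarios import ScenarioSet

__all__ = ["Violation", "ValidationReport", "validate_solution"]

_ATOL = 1e-6


@dataclass(frozen=True)
class Violation:
    family: str
    index: tuple
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    n_checks: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations

    def count(self, family: str) -> int:
        return sum(1 for v in self.violations if v.family == family)

    def summary(self) -> str:
        if self.ok:
            return f"clean ({self.n_checks} checks)"
        fams = sorted({v.family for v in self.violations})
        parts = ", ".join(f"{f}: {self.count(f)}" for f in fams)
        return f"{len(self.violations)} violations ({parts})"


def _flag(report, mask, family, detail, *index_arrays):
    idx = np.argwhere(mask)
    for tup in idx[:1000]:  # cap the listing, the count is what matters
        report.violations.append(
            Violation(family=family, index=tuple(int(i) for i in tup), detail=detail)
        )


def validate_solution(
    solution: Solution,
    config: NetworkConfig,
    scenarios: ScenarioSet,
    *,
    atol: float = _ATOL,
) -> ValidationReport:
    """Check all structural identities on a solved instance."""
    rep = ValidationReport()
    fs, ss = solution.first_stage, solution.second_stage
    K, T, S = scenarios.demand.shape
    lead = [h.lead_time_days for h in config.hospitals]
    rd, ly = ss.remaining_demand, ss.leftover

    def check(mask, family, detail):
        rep.n_checks += mask.size
        if mask.any():
            _flag(rep, mask, family, detail)

    # --- FIFO complementarity -------------------------------------------
    check(
        (rd * ly) > atol,
        "hospital_complementarity",
        "remaining demand and leftover stock both positive",
    )
    check(
        (ss.center_remaining_emergency * ss.center_left_emergency) > atol,
        "center_complementarity",
        "unserved emergency and kept stock both positive",
    )

    # --- arrivals implied by first-stage shipments ----------------------
    rehp = np.zeros((K, T, 3))
    for k in range(K):
        lt = lead[k]
        for t0 in range(T):
            for l_arr in (1, 2, 3):
                if l_arr + lt <= 3 and t0 - lt >= 0:
                    rehp[k, t0, l_arr - 1] = fs.shipments[k, t0 - lt, l_arr + lt - 1]

    # --- hospital cascade balances and conservation ---------------------
    oh = np.zeros((K, T, 2, S))
    for k in range(K):
        oh[k, 0, 0] = config.hospitals[k].opening_stock(1)
        oh[k, 0, 1] = config.hospitals[k].opening_stock(2)
    oh[:, 1:, 0, :] = ly[:, :-1, 1, :]
    oh[:, 1:, 1, :] = ly[:, :-1, 2, :]

    stage1 = rd[:, :, 0, :] - ly[:, :, 0, :] - (
        scenarios.demand - oh[:, :, 0, :] - rehp[:, :, 0][..., None]
    )
    stage2 = rd[:, :, 1, :] - ly[:, :, 1, :] - (
        rd[:, :, 0, :] - oh[:, :, 1, :] - rehp[:, :, 1][..., None]
    )
    stage3 = rd[:, :, 2, :] - ly[:, :, 2, :] - (
        rd[:, :, 1, :] - rehp[:, :, 2][..., None]
    )
    check(np.abs(stage1) > atol, "hospital_balance", "age-1 demand balance broken")
    check(np.abs(stage2) > atol, "hospital_balance", "age-2 demand balance broken")
    check(np.abs(stage3) > atol, "hospital_balance", "age-3 demand balance broken")

    # conservation: opening + received = issued + expired + closing
    served = scenarios.demand - rd[:, :, 2, :]
    received = rehp.sum(axis=2)[..., None]
    closing = ly[:, :, 1, :] + ly[:, :, 2, :]
    expired = ly[:, :, 0, :]
    balance = oh.sum(axis=2) + received - served - expired - closing
    check(np.abs(balance) > atol, "hospital_conservation", "units not conserved")

    # aging: next-day opening equals tonight's leftovers one age younger
    aging1 = oh[:, 1:, 0, :] - ly[:, :-1, 1, :]
    aging2 = oh[:, 1:, 1, :] - ly[:, :-1, 2, :]
    check(np.abs(aging1) > atol, "hospital_aging", "age-2 leftovers not carried")
    check(np.abs(aging2) > atol, "hospital_aging", "age-3 leftovers not carried")

    # --- nonanticipativity ----------------------------------------------
    # first-stage arrays carry no scenario axis by construction; verify the
    # shipment/order linkage that makes them scenario-invariant
    link = fs.shipments.sum(axis=2) - fs.orders
    check(np.abs(link) > atol, "nonanticipativity", "shipments do not cover orders")

    # --- blood-center identities ----------------------------------------
    shr_total = ss.center_external_regular.sum(axis=0)
    tshbc = ss.center_total_shortage
    check(
        np.abs(tshbc - (shr_total + ss.center_emergency_shortage)) > atol,
        "center_shortage_identity",
        "total shortage != regular external + emergency residual",
    )
    check(
        (ss.center_left_emergency - ss.center_left_regular) > atol,
        "center_stock",
        "stock grew during emergency fulfillment",
    )

    # regular fulfillment balances (ages by shelf: 1-2 carried, 3 fresh)
    from .simulate import realized_supply_receipts

    rebc = np.zeros((T, S))
    for s in range(S):
        rebc[:, s] = realized_supply_receipts(config, scenarios.supply[:, s])[1:]
    ohbc = np.zeros((T, 2, S))
    ohbc[0, 0] = config.blood_center.opening_stock(1)
    ohbc[0, 1] = config.blood_center.opening_stock(2)
    ohbc[1:, 0, :] = ss.center_left_emergency[:-1, 1, :]
    ohbc[1:, 1, :] = ss.center_left_emergency[:-1, 2, :]
    ship_by_age = fs.shipments.sum(axis=0)  # (T, 3) all-hospital totals
    b1 = (
        ss.center_left_regular[:, 0, :]
        + sum(
            fs.shipments[k, :, 0][:, None]
            for k in range(K)
            if lead[k] == 0
        )
        - ohbc[:, 0, :]
    )
    b2 = (
        ss.center_left_regular[:, 1, :]
        + sum(
            fs.shipments[k, :, 1][:, None]
            for k in range(K)
            if lead[k] <= 1
        )
        - ohbc[:, 1, :]
    )
    b3 = (
        ss.center_left_regular[:, 2, :]
        + ship_by_age[:, 2][:, None]
        - ss.center_external_regular.sum(axis=0)
        - rebc
    )
    for arr, name in ((b1, "age-1"), (b2, "age-2"), (b3, "age-3")):
        arr = np.asarray(arr, dtype=float)
        check(np.abs(arr) > atol, "center_balance", f"regular {name} balance broken")

    # emergency cascade balances
    em = rd[:, :, 2, :].sum(axis=0)
    e1 = (
        ss.center_remaining_emergency[:, 0, :]
        - ss.center_left_emergency[:, 0, :]
        - (em - ss.center_left_regular[:, 0, :])
    )
    e2 = (
        ss.center_remaining_emergency[:, 1, :]
        - ss.center_left_emergency[:, 1, :]
        - (
            ss.center_remaining_emergency[:, 0, :]
            - ss.center_left_regular[:, 1, :]
        )
    )
    e3 = (
        ss.center_remaining_emergency[:, 2, :]
        - ss.center_left_emergency[:, 2, :]
        - (
            ss.center_remaining_emergency[:, 1, :]
            - ss.center_left_regular[:, 2, :]
        )
    )
    for arr, name in ((e1, "stage-1"), (e2, "stage-2"), (e3, "stage-3")):
        check(np.abs(arr) > atol, "center_balance", f"emergency {name} balance broken")

    # integrality and sign
    for arr, name in (
        (rd, "remaining_demand"),
        (ly, "leftover"),
        (ss.center_left_regular, "center_left_regular"),
        (ss.center_left_emergency, "center_left_emergency"),
        (ss.center_remaining_emergency, "center_remaining_emergency"),
        (ss.center_external_regular, "center_external_regular"),
    ):
        check(arr < -atol, "sign", f"{name} negative")

    return rep
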