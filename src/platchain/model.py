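"""Two-stage stochastic MILP for the platelet supply chain.

The model decides, for every hospital and day, the regular order quantity
and the age composition of the blood center's shipment against it
(first stage, identical across scenarios — decided before demand and supply
realize), together with per-scenario FIFO issuing, shortage, expiry and
inventory cascades at both echelons (second stage). The objective is the
expected total cost over the horizon: fixed operating and shipping,
purchasing, holding, shortage (emergency procurement) and outdating at each
entity, weighted by scenario probability.

Structural reductions applied before the solver sees the problem (all are
identities, not approximations):

* the center's procurement equals the donor supply draw, so its orders and
  component-lab arrivals are data, not variables;
* arrivals at a hospital equal the center's shipment one lead time earlier
  (ages shifted by the transit time), and arrivals are first-stage, so all
  regular shipments are first-stage too;
* opening inventories equal the previous day's leftovers shifted one age
  younger, so on-hand variables are substituted by leftover variables;
* the center's shipment indicator follows from the arrival data.

FIFO behaviour is not imposed by explicit complementarity constraints: the
balance equations split each stage into "remaining demand" minus "leftover
stock", and strictly positive holding, shortage and outdating prices make
any solution with both sides positive strictly more expensive. Final-day
leftovers carry no price, so a solver may return non-complementary values
there among equally cheap optima; downstream reporting canonicalizes the
second stage by replaying the first-stage decisions through the event
simulator (identical cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .config import NetworkConfig
from .scenarios import ScenarioSet
from .simulate import realized_supply_receipts

__all__ = [
    "FirstStageDecisions",
    "SecondStageDecisions",
    "ModelInstance",
    "Solution",
    "build_model",
    "solve_model",
    "default_big_m",
]


def default_big_m(config: NetworkConfig) -> int:
    """Bound on any one day's shipment to a hospital.

    Three days' worth of aggregate mean demand plus six aggregate standard
    deviations: provably above any shipment an optimal policy uses, small
    enough not to hurt the linear relaxation badly.
    """
    mu = sum(h.demand.mean for h in config.hospitals)
    sd = sum(h.demand.sd for h in config.hospitals)
    return 3 * math.ceil(mu + 6 * sd)


@dataclass(frozen=True)
class FirstStageDecisions:
    """Scenario-invariant decisions.

    orders     (K, T) regular order quantity per hospital and day
    shipments  (K, T, 3) center shipment against that order by shipped age
               (the unit arrives ``lead_time`` days later, that much older)
    shipping_indicator  (K, T) 1 where a delivery is received
    """

    orders: np.ndarray
    shipments: np.ndarray
    shipping_indicator: np.ndarray


@dataclass(frozen=True)
class SecondStageDecisions:
    """Per-scenario cascade values (trailing scenario axis everywhere).

    remaining_demand / leftover   (K, T, 3, S) hospital FIFO stages
    center_left_regular           (T, 3, S) stock left after regular orders
    center_left_emergency         (T, 3, S) stock left after emergencies
    center_remaining_emergency    (T, 3, S) emergency demand still unmet
    center_external_regular       (K, T, S) externally procured units
                                  covering regular orders
    """

    remaining_demand: np.ndarray
    leftover: np.ndarray
    center_left_regular: np.ndarray
    center_left_emergency: np.ndarray
    center_remaining_emergency: np.ndarray
    center_external_regular: np.ndarray

    @property
    def hospital_shortage(self) -> np.ndarray:
        """(K, T, S) unmet demand, emergency-ordered the same day."""
        return self.remaining_demand[:, :, 2, :]

    @property
    def hospital_expired(self) -> np.ndarray:
        """(K, T, S) age-1 leftovers discarded at day end."""
        return self.leftover[:, :, 0, :]

    @property
    def center_emergency_shortage(self) -> np.ndarray:
        """(T, S) emergency demand procured outside the network."""
        return self.center_remaining_emergency[:, 2, :]

    @property
    def center_expired(self) -> np.ndarray:
        """(T, S) center age-1 stock discarded at day end."""
        return self.center_left_emergency[:, 0, :]

    @property
    def center_total_shortage(self) -> np.ndarray:
        """(T, S) regular external procurement plus emergency residual."""
        return self.center_external_regular.sum(axis=0) + self.center_emergency_shortage


class _Index:
    """Flat-column bookkeeping for the variable blocks."""

    def __init__(self, K: int, T: int, S: int):
        self.K, self.T, self.S = K, T, S
        self.n_orhp = K * T
        self.n_ship = K * T * 3
        self.n_bin = K * T
        self.first_stage = self.n_orhp + self.n_ship + self.n_bin
        # per-scenario block
        self._rd = 0
        self._ly = self._rd + K * T * 3
        self._lfr = self._ly + K * T * 3
        self._lfe = self._lfr + T * 3
        self._rsh = self._lfe + T * 3
        self._shr = self._rsh + T * 3
        self._zem = self._shr + K * T
        self._zh = self._zem + 2 * T + T  # BC stages 2,3 then stage 1
        self._zreg = self._zh + K * T * 3
        self.block = self._zreg + T
        self.n = self.first_stage + S * self.block

    # first stage -----------------------------------------------------------
    def orhp(self, k, t):
        return k * self.T + t

    def ship(self, k, t, l):
        return self.n_orhp + (k * self.T + t) * 3 + (l - 1)

    def binhp(self, k, t):
        return self.n_orhp + self.n_ship + k * self.T + t

    # second stage ----------------------------------------------------------
    def _base(self, s):
        return self.first_stage + s * self.block

    def rdhp(self, k, t, l, s):
        return self._base(s) + self._rd + (k * self.T + t) * 3 + (l - 1)

    def lyhp(self, k, t, l, s):
        return self._base(s) + self._ly + (k * self.T + t) * 3 + (l - 1)

    def lfrbc(self, t, l, s):
        return self._base(s) + self._lfr + t * 3 + (l - 1)

    def lfebc(self, t, l, s):
        return self._base(s) + self._lfe + t * 3 + (l - 1)

    def rshbc(self, t, l, s):
        return self._base(s) + self._rsh + t * 3 + (l - 1)

    def shrbc(self, k, t, s):
        return self._base(s) + self._shr + k * self.T + t

    def zem(self, t, l, s):
        """Emergency complementarity indicator for stage l in {1, 2, 3}."""
        if l == 1:
            return self._base(s) + self._zem + 2 * self.T + t
        return self._base(s) + self._zem + (l - 2) * self.T + t

    def zh(self, k, t, l, s):
        """Hospital FIFO complementarity indicator (strict mode only)."""
        return self._base(s) + self._zh + (k * self.T + t) * 3 + (l - 1)

    def zreg(self, t, s):
        """Regular-stage indicator: external procurement xor kept arrivals."""
        return self._base(s) + self._zreg + t


@dataclass
class ModelInstance:
    """Assembled MILP ready for the solver."""

    config: NetworkConfig
    scenarios: ScenarioSet
    c: np.ndarray
    constant: float
    A_eq: sp.csr_matrix
    b_eq: np.ndarray
    A_ub: sp.csr_matrix
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    index: _Index
    big_m: int
    rebc: np.ndarray  # (T+1, S) component-lab arrivals, day-1-based rows 1..T
    options: dict[str, Any] = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return int(self.c.size)

    @property
    def n_constraints(self) -> int:
        return int(self.b_eq.size + self.b_ub.size)

    def objective_of(self, x: np.ndarray) -> float:
        return float(self.c @ x) + self.constant


def _order_day_allowed(config: NetworkConfig, k: int, t: int, T: int) -> bool:
    """Day ``t`` (1-based) accepts an order from hospital ``k``.

    Orders are allowed on review days only; orders whose delivery would
    arrive after the horizon are fixed to zero (they could only add cost).
    """
    h = config.hospitals[k]
    return t % h.review_period_days == 0 and t + h.lead_time_days <= T


def build_model(
    config: NetworkConfig,
    scenarios: ScenarioSet,
    *,
    price_emergency_shortage: bool = False,
    strict_fifo: bool | str = True,
    relax_integrality: bool = False,
    big_m: int | None = None,
    options: dict[str, Any] | None = None,
    center_arrivals_override: dict[int, int] | None = None,
    hospital_arrivals: dict[tuple[int, int], Any] | None = None,
) -> ModelInstance:
    """Assemble the stochastic program over ``scenarios``.

    ``price_emergency_shortage`` additionally charges the center's shortage
    price on the emergency residual (by default only external procurement
    for regular orders is priced at the center; the hospitals already pay
    the emergency-procurement price for their shortage units).

    ``strict_fifo`` adds indicator constraints forcing FIFO cascade stages
    to be complementary (remaining demand x leftover stock = 0). Strictly
    positive holding/shortage/outdating prices make most deviations
    unprofitable on their own, but two families are genuinely attractive
    to a cost minimizer and otherwise possible: discarding doomed stock a
    day early (saves holding, same outdating), and hoarding center stock
    against tomorrow's committed shipments by procuring externally or
    declaring emergency demand unserved. Three levels:

    ``"full"`` (or ``True``, the default) — indicators on every stage; the
    optimum is exactly event-consistent and the replay oracle reproduces
    the objective to machine precision.

    ``"stock"`` — indicators on the emergency stages that could otherwise
    hoard or fabricate center stock; the replayed cost of the solved first
    stage exceeds the objective by at most the value of the remaining
    deviations (observed ~0.02%), giving a two-sided bound on the exact
    optimum at a fraction of the solve time. A gap-terminated incumbent
    may still pre-buy against a committed aged shipment (a plan the event
    rules cannot execute verbatim);
    :func:`platchain.optimize.harden_shipments` repairs exactly those
    units, and :func:`platchain.optimize.optimize` applies it.

    ``"off"`` (or ``False``) — balance equations and valid cuts only.

    ``relax_integrality`` builds the LP relaxation — useful for fast
    property tests, clearly not the unit-valued model.

    ``center_arrivals_override`` (1-based day -> units) and
    ``hospital_arrivals`` ((hospital index, 1-based day) -> length-3 array
    of units by arrival age) inject known in-transit deliveries, e.g. when
    a rolling-horizon driver re-solves mid-stream.
    """
    K, T, S = scenarios.demand.shape
    if K != config.n_hospitals or T != config.horizon_days or S != config.n_scenarios:
        raise ValueError(
            f"scenario dimensions {(K, T, S)} do not match the configuration "
            f"({config.n_hospitals}, {config.horizon_days}, {config.n_scenarios})"
        )
    idx = _Index(K, T, S)
    M = default_big_m(config) if big_m is None else int(big_m)
    pb = scenarios.probabilities
    lead = [h.lead_time_days for h in config.hospitals]

    rebc = np.zeros((T + 1, S), dtype=np.int64)
    for s in range(S):
        rebc[:, s] = realized_supply_receipts(config, scenarios.supply[:, s])
    if center_arrivals_override:
        for day, units in center_arrivals_override.items():
            if not 1 <= day <= config.blood_center.lead_time_days:
                raise ValueError(
                    "center arrival overrides only apply to days still "
                    "covered by pre-horizon orders"
                )
            rebc[day, :] = int(units)

    def warm_arrival(k: int, t0: int, l: int) -> float:
        if not hospital_arrivals:
            return 0.0
        arr = hospital_arrivals.get((k, t0 + 1))
        return 0.0 if arr is None else float(arr[l - 1])

    lb = np.zeros(idx.n)
    ub = np.full(idx.n, np.inf)

    # fix structurally zero first-stage variables via zero upper bounds
    for k in range(K):
        for t0 in range(T):
            allowed = _order_day_allowed(config, k, t0 + 1, T)
            if not allowed:
                ub[idx.orhp(k, t0)] = 0.0
                ub[idx.binhp(k, t0)] = 0.0
                for l in (1, 2, 3):
                    ub[idx.ship(k, t0, l)] = 0.0
            else:
                ub[idx.binhp(k, t0)] = 1.0
                for l in (1, 2, 3):
                    if l <= lead[k]:  # would expire in transit
                        ub[idx.ship(k, t0, l)] = 0.0
    # no shipment day -> no external procurement against it
    for s in range(S):
        for k in range(K):
            for t0 in range(T):
                if ub[idx.ship(k, t0, 3)] == 0.0:
                    ub[idx.shrbc(k, t0, s)] = 0.0
    # remaining demand can never exceed the day's demand (valid event cut)
    for s in range(S):
        for k in range(K):
            for t0 in range(T):
                cap = float(scenarios.demand[k, t0, s])
                for l in (1, 2, 3):
                    ub[idx.rdhp(k, t0, l, s)] = cap
    if strict_fifo is True:
        strict_fifo = "full"
    elif strict_fifo is False:
        strict_fifo = "off"
    if strict_fifo not in ("full", "stock", "off"):
        raise ValueError("strict_fifo must be 'full', 'stock', 'off' or a bool")
    full = strict_fifo == "full"
    stock_guard = strict_fifo in ("full", "stock")
    # complementarity indicators are binary where used, fixed to 0 elsewhere
    for s in range(S):
        for t0 in range(T):
            # stages 2-3 guard center stock; stage 1 stock expires anyway
            ub[idx.zem(t0, 2, s)] = 1.0 if stock_guard else 0.0
            ub[idx.zem(t0, 3, s)] = 1.0 if stock_guard else 0.0
            ub[idx.zem(t0, 1, s)] = 1.0 if full else 0.0
            ub[idx.zreg(t0, s)] = 1.0 if full else 0.0
            for k in range(K):
                for l in (1, 2, 3):
                    ub[idx.zh(k, t0, l, s)] = 1.0 if full else 0.0

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b_eq: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    def rehp_col(k: int, t0: int, l: int) -> int | None:
        """Column of the arrival of age ``l`` at hospital ``k`` on day t0."""
        lt = lead[k]
        if l + lt > 3 or t0 - lt < 0:
            return None
        col = idx.ship(k, t0 - lt, l + lt)
        return None if ub[col] == 0.0 else col

    r = 0
    ini_h = [
        (config.hospitals[k].opening_stock(1), config.hospitals[k].opening_stock(2))
        for k in range(K)
    ]
    ini_bc = (
        config.blood_center.opening_stock(1),
        config.blood_center.opening_stock(2),
    )

    # hospital FIFO cascades -------------------------------------------------
    for s in range(S):
        for k in range(K):
            for t0 in range(T):
                # age-1 stage: demand vs opening age-1 stock + age-1 arrivals
                add(r, idx.rdhp(k, t0, 1, s), 1.0)
                add(r, idx.lyhp(k, t0, 1, s), -1.0)
                rhs = float(scenarios.demand[k, t0, s]) - warm_arrival(k, t0, 1)
                if t0 > 0:
                    add(r, idx.lyhp(k, t0 - 1, 2, s), 1.0)
                else:
                    rhs -= ini_h[k][0]
                col = rehp_col(k, t0, 1)
                if col is not None:
                    add(r, col, 1.0)
                b_eq.append(rhs)
                r += 1
                # age-2 stage
                add(r, idx.rdhp(k, t0, 2, s), 1.0)
                add(r, idx.lyhp(k, t0, 2, s), -1.0)
                add(r, idx.rdhp(k, t0, 1, s), -1.0)
                rhs = -warm_arrival(k, t0, 2)
                if t0 > 0:
                    add(r, idx.lyhp(k, t0 - 1, 3, s), 1.0)
                else:
                    rhs -= ini_h[k][1]
                col = rehp_col(k, t0, 2)
                if col is not None:
                    add(r, col, 1.0)
                b_eq.append(rhs)
                r += 1
                # age-3 stage: only fresh arrivals remain
                add(r, idx.rdhp(k, t0, 3, s), 1.0)
                add(r, idx.lyhp(k, t0, 3, s), -1.0)
                add(r, idx.rdhp(k, t0, 2, s), -1.0)
                col = rehp_col(k, t0, 3)
                if col is not None:
                    add(r, col, 1.0)
                b_eq.append(-warm_arrival(k, t0, 3))
                r += 1

    # blood-center regular fulfillment and emergency cascade -----------------
    for s in range(S):
        for t0 in range(T):
            # ages 1 and 2 ship from carried stock
            for l in (1, 2):
                for k in range(K):
                    col = idx.ship(k, t0, l)
                    if ub[col] != 0.0:
                        add(r, col, 1.0)
                add(r, idx.lfrbc(t0, l, s), 1.0)
                rhs = 0.0
                if t0 > 0:
                    add(r, idx.lfebc(t0 - 1, l + 1, s), -1.0)
                else:
                    rhs = float(ini_bc[l - 1])
                b_eq.append(rhs)
                r += 1
            # age 3 ships from the day's arrivals; the overflow is procured
            for k in range(K):
                col = idx.ship(k, t0, 3)
                if ub[col] != 0.0:
                    add(r, col, 1.0)
                if ub[idx.shrbc(k, t0, s)] != 0.0:
                    add(r, idx.shrbc(k, t0, s), -1.0)
            add(r, idx.lfrbc(t0, 3, s), 1.0)
            b_eq.append(float(rebc[t0 + 1, s]))
            r += 1
            # emergency demand cascades through the leftover stock
            for k in range(K):
                add(r, idx.rdhp(k, t0, 3, s), 1.0)
            add(r, idx.lfrbc(t0, 1, s), -1.0)
            add(r, idx.rshbc(t0, 1, s), -1.0)
            add(r, idx.lfebc(t0, 1, s), 1.0)
            b_eq.append(0.0)
            r += 1
            for l in (2, 3):
                add(r, idx.rshbc(t0, l - 1, s), 1.0)
                add(r, idx.lfrbc(t0, l, s), -1.0)
                add(r, idx.rshbc(t0, l, s), -1.0)
                add(r, idx.lfebc(t0, l, s), 1.0)
                b_eq.append(0.0)
                r += 1

    # shipments cover the order (scenario-invariant, stated once) ------------
    for k in range(K):
        for t0 in range(T):
            if ub[idx.orhp(k, t0)] == 0.0:
                continue
            for l in (1, 2, 3):
                col = idx.ship(k, t0, l)
                if ub[col] != 0.0:
                    add(r, col, 1.0)
            add(r, idx.orhp(k, t0), -1.0)
            b_eq.append(0.0)
            r += 1

    n_eq = r
    A_eq = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_eq, idx.n)
    )

    # inequalities: big-M shipment indicators, procurement caps --------------
    rows, cols, vals = [], [], []
    b_ub: list[float] = []
    r = 0
    for k in range(K):
        for t0 in range(T):
            if ub[idx.orhp(k, t0)] == 0.0:
                continue
            add(r, idx.orhp(k, t0), 1.0)
            add(r, idx.binhp(k, t0), -float(M))
            b_ub.append(0.0)
            r += 1
    for s in range(S):
        for k in range(K):
            for t0 in range(T):
                if ub[idx.shrbc(k, t0, s)] == 0.0:
                    continue
                add(r, idx.shrbc(k, t0, s), 1.0)
                add(r, idx.ship(k, t0, 3), -1.0)
                b_ub.append(0.0)
                r += 1
    # Valid event cuts, always on. They are implied by the cascades'
    # intended min/max semantics but not by the linearized balances:
    # (i) remaining demand shrinks along the age cascade, and
    # (ii) the stock left after the emergency round never exceeds the stock
    #      left after the regular round (no inventory out of nothing).
    for s in range(S):
        for t0 in range(T):
            for k in range(K):
                for l in (2, 3):
                    add(r, idx.rdhp(k, t0, l, s), 1.0)
                    add(r, idx.rdhp(k, t0, l - 1, s), -1.0)
                    b_ub.append(0.0)
                    r += 1
            for l in (1, 2, 3):
                add(r, idx.lfebc(t0, l, s), 1.0)
                add(r, idx.lfrbc(t0, l, s), -1.0)
                b_ub.append(0.0)
                r += 1
    # Strict-FIFO indicators: each cascade stage is either out of stock or
    # fully served, never both short and holding. Caps are data-driven
    # where possible (remaining demand <= the day's demand; kept center
    # stock <= what can physically be on that shelf) and fall back on the
    # shipment bound for hospital leftovers.
    bc_ini = config.blood_center.initial_inventory
    for s in range(S):
        for t0 in range(T):
            if full:
                for k in range(K):
                    d_cap = float(scenarios.demand[k, t0, s])
                    if d_cap == 0.0:
                        continue  # no demand -> remaining demand is 0 by bound
                    for l in (1, 2, 3):
                        add(r, idx.rdhp(k, t0, l, s), 1.0)
                        add(r, idx.zh(k, t0, l, s), -d_cap)
                        b_ub.append(0.0)
                        r += 1
                        ly_cap = float(M + ini_h[k][0] + ini_h[k][1])
                        add(r, idx.lyhp(k, t0, l, s), 1.0)
                        add(r, idx.zh(k, t0, l, s), ly_cap)
                        b_ub.append(ly_cap)
                        r += 1
            if full and rebc[t0 + 1, s] > 0:
                # regular stage: never procure externally while fresh
                # arrivals are left unshipped (the solver would otherwise
                # pre-buy against a committed aged shipment tomorrow)
                any_shr = False
                for k in range(K):
                    if ub[idx.shrbc(k, t0, s)] != 0.0:
                        add(r, idx.shrbc(k, t0, s), 1.0)
                        any_shr = True
                if any_shr:
                    add(r, idx.zreg(t0, s), -float(K * M))
                    b_ub.append(0.0)
                    r += 1
                    add(r, idx.lfrbc(t0, 3, s), 1.0)
                    add(r, idx.zreg(t0, s), float(rebc[t0 + 1, s]))
                    b_ub.append(float(rebc[t0 + 1, s]))
                    r += 1
            e_cap = float(scenarios.demand[:, t0, s].sum())
            if e_cap == 0.0 or not stock_guard:
                continue
            # shelf-content caps: age-3 holds today's arrivals, age-2
            # yesterday's, age-1 the day before yesterday's
            s_cap = {
                3: float(rebc[t0 + 1, s]),
                2: float(rebc[t0, s]) if t0 >= 1 else float(bc_ini.get(2, 0)),
                1: float(rebc[t0 - 1, s]) if t0 >= 2 else float(
                    bc_ini.get(1, 0) if t0 == 0 else bc_ini.get(2, 0)
                ),
            }
            for l in (1, 2, 3):
                if s_cap[l] == 0.0:
                    continue  # empty shelf -> nothing to keep back
                if l == 1 and not full:
                    continue  # age-1 stage only reshuffles cost, never stock
                add(r, idx.rshbc(t0, l, s), 1.0)
                add(r, idx.zem(t0, l, s), -e_cap)
                b_ub.append(0.0)
                r += 1
                add(r, idx.lfebc(t0, l, s), 1.0)
                add(r, idx.zem(t0, l, s), s_cap[l])
                b_ub.append(s_cap[l])
                r += 1
    A_ub = sp.csr_matrix((vals, (rows, cols)), shape=(r, idx.n))

    # objective ---------------------------------------------------------------
    c = np.zeros(idx.n)
    costs = config.costs
    constant = 0.0
    for k in range(K):
        ck = costs.hospitals[k]
        constant += ck.fixed_operating * T
        constant += ck.holding * (ini_h[k][0] + ini_h[k][1])
        for t0 in range(T):
            c[idx.orhp(k, t0)] += ck.purchase
            c[idx.binhp(k, t0)] += ck.fixed_shipping
            for s in range(S):
                c[idx.rdhp(k, t0, 3, s)] += pb[s] * ck.shortage
                c[idx.lyhp(k, t0, 1, s)] += pb[s] * ck.outdating
                if t0 < T - 1:  # tomorrow's opening stock
                    c[idx.lyhp(k, t0, 2, s)] += pb[s] * ck.holding
                    c[idx.lyhp(k, t0, 3, s)] += pb[s] * ck.holding
    cb = costs.blood_center
    constant += cb.fixed_operating * T
    constant += cb.holding * (ini_bc[0] + ini_bc[1])
    constant += cb.fixed_shipping * float(
        pb @ (rebc[1:, :] > 0).sum(axis=0).astype(float)
    )
    for t0 in range(T):
        for s in range(S):
            c[idx.lfebc(t0, 1, s)] += pb[s] * cb.outdating
            if t0 < T - 1:
                c[idx.lfebc(t0, 2, s)] += pb[s] * cb.holding
                c[idx.lfebc(t0, 3, s)] += pb[s] * cb.holding
            if price_emergency_shortage:
                c[idx.rshbc(t0, 3, s)] += pb[s] * cb.shortage
            for k in range(K):
                if ub[idx.shrbc(k, t0, s)] != 0.0:
                    c[idx.shrbc(k, t0, s)] += pb[s] * cb.shortage

    integrality = np.zeros(idx.n) if relax_integrality else np.ones(idx.n)

    return ModelInstance(
        config=config,
        scenarios=scenarios,
        c=c,
        constant=constant,
        A_eq=A_eq,
        b_eq=np.asarray(b_eq),
        A_ub=A_ub,
        b_ub=np.asarray(b_ub),
        lb=lb,
        ub=ub,
        integrality=integrality,
        index=idx,
        big_m=M,
        rebc=rebc,
        options=dict(options or {}),
    )


@dataclass
class Solution:
    """Solved decisions plus solver metadata."""

    first_stage: FirstStageDecisions
    second_stage: SecondStageDecisions
    objective_value: float
    status: str
    mip_gap: float
    solver_message: str = ""
    #: certified lower bound on the exact optimum (equals the objective for
    #: exactly solved models; strictly below it for certified workflows)
    lower_bound: float = float("nan")

    def summary(self) -> dict[str, Any]:
        return {
            "objective_value": self.objective_value,
            "status": self.status,
            "mip_gap": self.mip_gap,
            "lower_bound": self.lower_bound,
        }

    def to_csv(self, out_dir) -> list[str]:
        """Write one long-format CSV per decision family plus a summary.

        Columns are (hospital|day|age|scenario, value) as applicable; days
        are 1-based. Returns the file names written.
        """
        import json
        from pathlib import Path

        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[str] = []

        def dump(name, array, axes):
            frame = pd.DataFrame(
                [
                    dict(zip(axes, idx)) | {"value": array[idx]}
                    for idx in np.ndindex(array.shape)
                    if array[idx]
                ]
            )
            if frame.empty:
                frame = pd.DataFrame(columns=[*axes, "value"])
            for ax in axes:
                if ax in ("day", "age", "hospital") and not frame.empty:
                    frame[ax] = frame[ax] + 1  # 1-based labels
            frame.to_csv(out / f"{name}.csv", index=False)
            written.append(f"{name}.csv")

        fs, ss = self.first_stage, self.second_stage
        dump("orders", fs.orders, ("hospital", "day"))
        dump("shipments", fs.shipments, ("hospital", "day", "age"))
        dump("remaining_demand", ss.remaining_demand, ("hospital", "day", "age", "scenario"))
        dump("leftover", ss.leftover, ("hospital", "day", "age", "scenario"))
        dump("center_left_regular", ss.center_left_regular, ("day", "age", "scenario"))
        dump("center_left_emergency", ss.center_left_emergency, ("day", "age", "scenario"))
        dump("center_remaining_emergency", ss.center_remaining_emergency, ("day", "age", "scenario"))
        dump("center_external_regular", ss.center_external_regular, ("hospital", "day", "scenario"))
        (out / "solution.json").write_text(json.dumps(self.summary(), indent=2))
        written.append("solution.json")
        return written


def _extract(model: ModelInstance, x: np.ndarray) -> tuple[FirstStageDecisions, SecondStageDecisions]:
    idx = model.index
    K, T, S = idx.K, idx.T, idx.S
    orders = np.zeros((K, T), dtype=np.int64)
    ships = np.zeros((K, T, 3), dtype=np.int64)
    bins = np.zeros((K, T), dtype=np.int64)
    for k in range(K):
        for t0 in range(T):
            orders[k, t0] = round(float(x[idx.orhp(k, t0)]))
            bins[k, t0] = round(float(x[idx.binhp(k, t0)]))
            for l in (1, 2, 3):
                ships[k, t0, l - 1] = round(float(x[idx.ship(k, t0, l)]))

    rd = np.zeros((K, T, 3, S))
    ly = np.zeros((K, T, 3, S))
    lfr = np.zeros((T, 3, S))
    lfe = np.zeros((T, 3, S))
    rsh = np.zeros((T, 3, S))
    shr = np.zeros((K, T, S))
    for s in range(S):
        for t0 in range(T):
            for l in (1, 2, 3):
                lfr[t0, l - 1, s] = x[idx.lfrbc(t0, l, s)]
                lfe[t0, l - 1, s] = x[idx.lfebc(t0, l, s)]
                rsh[t0, l - 1, s] = x[idx.rshbc(t0, l, s)]
                for k in range(K):
                    rd[k, t0, l - 1, s] = x[idx.rdhp(k, t0, l, s)]
                    ly[k, t0, l - 1, s] = x[idx.lyhp(k, t0, l, s)]
            for k in range(K):
                shr[k, t0, s] = x[idx.shrbc(k, t0, s)]
    if model.integrality.any():
        rd, ly, lfr, lfe, rsh, shr = (
            np.rint(a) for a in (rd, ly, lfr, lfe, rsh, shr)
        )
    first = FirstStageDecisions(orders=orders, shipments=ships, shipping_indicator=bins)
    second = SecondStageDecisions(
        remaining_demand=rd,
        leftover=ly,
        center_left_regular=lfr,
        center_left_emergency=lfe,
        center_remaining_emergency=rsh,
        center_external_regular=shr,
    )
    return first, second


_STATUS = {0: "optimal", 1: "iteration_or_time_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_model(
    model: ModelInstance,
    *,
    mip_rel_gap: float | None = None,
    time_limit: float | None = None,
) -> Solution:
    """Solve ``model`` with HiGHS (through scipy) and extract the decisions.

    Raises ``RuntimeError`` on infeasibility or when the time limit passes
    without an incumbent. Single-threaded and deterministic for a fixed
    model and options.
    """
    opts: dict[str, Any] = {}
    gap = model.options.get("mip_rel_gap") if mip_rel_gap is None else mip_rel_gap
    tl = model.options.get("time_limit") if time_limit is None else time_limit
    if gap is not None:
        opts["mip_rel_gap"] = float(gap)
    if tl is not None:
        opts["time_limit"] = float(tl)

    constraints = []
    if model.b_eq.size:
        constraints.append(LinearConstraint(model.A_eq, model.b_eq, model.b_eq))
    if model.b_ub.size:
        constraints.append(
            LinearConstraint(model.A_ub, -np.inf, model.b_ub)
        )
    res = milp(
        c=model.c,
        constraints=constraints,
        integrality=model.integrality,
        bounds=Bounds(model.lb, model.ub),
        options=opts,
    )
    status = _STATUS.get(res.status, "error")
    if res.x is None:
        if status == "infeasible":
            raise RuntimeError(
                "model is infeasible; check initial inventories, lead times "
                "and review periods for inconsistent index combinations"
            )
        raise RuntimeError(f"solver returned no incumbent: {res.message}")
    first, second = _extract(model, res.x)
    gap_out = float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else 0.0
    objective = model.objective_of(res.x)
    dual = getattr(res, "mip_dual_bound", None)
    lower = objective if dual is None else float(dual) + model.constant
    return Solution(
        first_stage=first,
        second_stage=second,
        objective_value=objective,
        status=status,
        mip_gap=gap_out,
        solver_message=str(res.message),
        lower_bound=lower,
    )
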