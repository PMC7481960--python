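"""Network, cost, and distribution configuration for the platelet supply chain.

The supply chain has one blood center serving ``K`` hospitals. Platelets
arrive at the blood center with a three-day remaining shelf life; a unit
shipped to a hospital with lead time ``LTHP_k`` loses ``LTHP_k`` days in
transit, so only ages ``l`` with ``l + LTHP_k <= 3`` may ever be shipped and
hospital lead times beyond two days are impossible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "DistributionSpec",
    "HospitalConfig",
    "BloodCenterConfig",
    "EntityCosts",
    "CostParams",
    "NetworkConfig",
    "load_config",
    "base_case_config",
]

MAX_SHELF_LIFE = 3


class DistributionSpec(BaseModel):
    """Normal demand/supply distribution, in platelet units per day."""

    mean: float = Field(ge=0)
    sd: float = Field(ge=0)

    def cv(self) -> float:
        """Coefficient of variation sd/mean; requires a positive mean."""
        if self.mean <= 0:
            raise ValueError("cv() undefined for mean <= 0")
        return self.sd / self.mean


def _check_initial_inventory(inv: Mapping[int, int]) -> dict[int, int]:
    out = {}
    for l, units in inv.items():
        l = int(l)
        if l not in (1, 2):
            raise ValueError(
                "initial_inventory keys must be shelf lives in {1, 2}: "
                "carry-over stock has at most two days of life"
            )
        if units < 0:
            raise ValueError(f"initial_inventory[{l}] must be >= 0")
        out[l] = int(units)
    return out


class HospitalConfig(BaseModel):
    """One hospital: lead time, review period, starting stock, demand."""

    id: int
    lead_time_days: int
    review_period_days: int = Field(ge=1)
    initial_inventory: dict[int, int] = Field(default_factory=dict)
    demand: DistributionSpec

    @field_validator("lead_time_days")
    @classmethod
    def _lead_time_in_range(cls, v: int) -> int:
        if v not in (0, 1, 2):
            raise ValueError(
                "hospital lead_time_days must be 0, 1 or 2: platelets ship "
                "with at most a 3-day shelf life and must arrive usable"
            )
        return v

    @field_validator("initial_inventory")
    @classmethod
    def _inv_ok(cls, v):
        return _check_initial_inventory(v)

    def opening_stock(self, shelf_life: int) -> int:
        return self.initial_inventory.get(shelf_life, 0)


class BloodCenterConfig(BaseModel):
    """The blood center: procurement lead time, review period, stock, supply."""

    lead_time_days: int = Field(ge=1)
    review_period_days: int = Field(ge=1)
    initial_inventory: dict[int, int] = Field(default_factory=dict)
    supply: DistributionSpec

    @field_validator("initial_inventory")
    @classmethod
    def _inv_ok(cls, v):
        return _check_initial_inventory(v)

    def opening_stock(self, shelf_life: int) -> int:
        return self.initial_inventory.get(shelf_life, 0)


class EntityCosts(BaseModel):
    """The cost coefficients charged at one entity (hospital or center).

    fixed_operating  $/day, charged every day regardless of decisions
    fixed_shipping   $/shipment, charged when a delivery is received
    purchase         $/unit ordered (processing/testing at the center; the
                     center's purchase cost is excluded from the objective
                     because hospitals pay for procurement)
    holding          $/unit/day of opening on-hand inventory
    shortage         $/unit of unmet demand, i.e. the emergency-procurement
                     price per unit
    outdating        $/unit expiring unused
    """

    fixed_operating: float = Field(ge=0, default=0.0)
    fixed_shipping: float = Field(ge=0)
    purchase: float = Field(ge=0)
    holding: float = Field(ge=0)
    shortage: float = Field(ge=0)
    outdating: float = Field(ge=0)

    def scaled(self, field: str, factor: float) -> "EntityCosts":
        data = self.model_dump()
        data[field] = data[field] * factor
        return EntityCosts(**data)


class CostParams(BaseModel):
    """All cost coefficients: one block per hospital plus the center's."""

    hospitals: list[EntityCosts]
    blood_center: EntityCosts

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.hospitals:
            raise ValueError("costs.hospitals must not be empty")
        return self


class NetworkConfig(BaseModel):
    """Full problem instance: network, costs, horizon and scenario count."""

    hospitals: list[HospitalConfig]
    blood_center: BloodCenterConfig
    costs: CostParams
    horizon_days: int = Field(ge=1)
    n_scenarios: int = Field(ge=1)
    seed: int = 0
    # "primed": pre-horizon procurement at the supply mean fills the
    # center's arrival stream for days 1..lead_time (steady-state start);
    # "cold": nothing arrives until an in-horizon order can (day lead_time+1)
    supply_pipeline: str = "primed"

    @field_validator("supply_pipeline")
    @classmethod
    def _pipeline_ok(cls, v: str) -> str:
        if v not in ("primed", "cold"):
            raise ValueError("supply_pipeline must be 'primed' or 'cold'")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if not self.hospitals:
            raise ValueError("network must contain at least one hospital")
        if len(self.costs.hospitals) != len(self.hospitals):
            raise ValueError(
                f"costs.hospitals has {len(self.costs.hospitals)} entries "
                f"for {len(self.hospitals)} hospitals"
            )
        max_rp = max(
            [h.review_period_days for h in self.hospitals]
            + [self.blood_center.review_period_days]
        )
        if self.horizon_days < max_rp:
            raise ValueError("horizon_days must cover the longest review period")
        if self.horizon_days < self.blood_center.lead_time_days:
            raise ValueError("horizon_days must cover the blood-center lead time")
        return self

    @property
    def n_hospitals(self) -> int:
        return len(self.hospitals)

    def with_costs(self, costs: CostParams) -> "NetworkConfig":
        return self.model_copy(update={"costs": costs})


def load_config(path: str | Path) -> NetworkConfig:
    """Read and validate a YAML or JSON network configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return NetworkConfig(**data)


def base_case_config(
    horizon_days: int = 300,
    n_scenarios: int = 100,
    seed: int = 0,
) -> NetworkConfig:
    """The two-hospital base-case instance.

    Hospital demands N(200, 32) and N(100, 16) with lead times 1 and 2 days;
    blood-center supply N(225, 36) with a 5-day procurement lead time;
    review period one day everywhere. Initial inventories default to one
    mean day of demand (supply) at two days of remaining shelf life — the
    stock level a daily-ordering entity would carry into any typical day.
    """
    hospital_costs = EntityCosts(
        fixed_operating=0.0,
        fixed_shipping=113.0,
        purchase=650.0,
        holding=130.0,
        shortage=3250.0,
        outdating=650.0,
    )
    hospital2_costs = hospital_costs.model_copy(update={"fixed_shipping": 225.0})
    center_costs = EntityCosts(
        fixed_operating=0.0,
        fixed_shipping=1125.0,
        purchase=538.0,
        holding=108.0,
        shortage=2690.0,
        outdating=538.0,
    )
    return NetworkConfig(
        hospitals=[
            HospitalConfig(
                id=1,
                lead_time_days=1,
                review_period_days=1,
                initial_inventory={2: 200},
                demand=DistributionSpec(mean=200, sd=32),
            ),
            HospitalConfig(
                id=2,
                lead_time_days=2,
                review_period_days=1,
                initial_inventory={2: 100},
                demand=DistributionSpec(mean=100, sd=16),
            ),
        ],
        blood_center=BloodCenterConfig(
            lead_time_days=5,
            review_period_days=1,
            initial_inventory={2: 225},
            supply=DistributionSpec(mean=225, sd=36),
        ),
        costs=CostParams(
            hospitals=[hospital_costs, hospital2_costs],
            blood_center=center_costs,
        ),
        horizon_days=horizon_days,
        n_scenarios=n_scenarios,
        seed=seed,
    )
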