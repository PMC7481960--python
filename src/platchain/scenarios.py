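"""Scenario generation for demand and supply uncertainty.

A scenario is one joint realization of every hospital's daily demand and the
blood center's daily raw-platelet supply over the whole horizon. Scenarios
are sampled i.i.d. from the configured normal distributions, truncated at
zero and rounded to whole units (all flows are integer platelet units), and
carry uniform probabilities ``1/S``.

Each entity draws from its own child generator spawned deterministically
from the master seed (hospitals in index order, then the blood center), so
adding a hospital to a configuration never reshuffles the draws of the
entities already present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DistributionSpec, NetworkConfig

__all__ = ["ScenarioSet", "generate_scenarios", "apply_cv_setting"]


@dataclass(frozen=True)
class ScenarioSet:
    """Sampled demand/supply paths.

    demand        int array of shape (K, T, S), units
    supply        int array of shape (T, S), units
    probabilities float array of shape (S,), summing to one
    """

    demand: np.ndarray
    supply: np.ndarray
    probabilities: np.ndarray
    seed: int = 0

    def __post_init__(self):
        if self.demand.ndim != 3 or self.supply.ndim != 2:
            raise ValueError("demand must be (K,T,S) and supply (T,S)")
        if self.demand.shape[1:] != self.supply.shape:
            raise ValueError("demand and supply disagree on (T, S)")
        if self.probabilities.shape != (self.demand.shape[2],):
            raise ValueError("probabilities must have one entry per scenario")
        if (self.demand < 0).any() or (self.supply < 0).any():
            raise ValueError("demand and supply must be nonnegative")
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-12:
            raise ValueError("scenario probabilities must sum to 1")

    @property
    def n_hospitals(self) -> int:
        return self.demand.shape[0]

    @property
    def horizon_days(self) -> int:
        return self.demand.shape[1]

    @property
    def n_scenarios(self) -> int:
        return self.demand.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (entity, day, scenario, value) for audits."""
        K, T, S = self.demand.shape
        rows = []
        for k in range(K):
            kk, tt, ss = np.meshgrid(
                [f"hospital_{k + 1}"], np.arange(1, T + 1), np.arange(S),
                indexing="ij",
            )
            rows.append(
                pd.DataFrame(
                    {
                        "entity": kk.ravel(),
                        "day": tt.ravel(),
                        "scenario": ss.ravel(),
                        "value": self.demand[k].ravel(),
                    }
                )
            )
        tt, ss = np.meshgrid(np.arange(1, T + 1), np.arange(S), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "entity": "blood_center",
                    "day": tt.ravel(),
                    "scenario": ss.ravel(),
                    "value": self.supply.ravel(),
                }
            )
        )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = 0) -> "ScenarioSet":
        hospitals = sorted(
            e for e in frame["entity"].unique() if e.startswith("hospital_")
        )
        T = int(frame["day"].max())
        S = int(frame["scenario"].max()) + 1
        demand = np.zeros((len(hospitals), T, S), dtype=np.int64)
        for k, name in enumerate(hospitals):
            sub = frame[frame["entity"] == name]
            demand[k, sub["day"] - 1, sub["scenario"]] = sub["value"]
        supply = np.zeros((T, S), dtype=np.int64)
        sub = frame[frame["entity"] == "blood_center"]
        supply[sub["day"] - 1, sub["scenario"]] = sub["value"]
        return cls(
            demand=demand,
            supply=supply,
            probabilities=np.full(S, 1.0 / S),
            seed=seed,
        )

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "ScenarioSet":
        return cls.from_frame(pd.read_csv(path), seed=seed)


def _sample(rng: np.random.Generator, dist: DistributionSpec, shape) -> np.ndarray:
    draws = rng.normal(dist.mean, dist.sd, size=shape)
    return np.rint(np.clip(draws, 0.0, None)).astype(np.int64)


def generate_scenarios(config: NetworkConfig, seed: int | None = None) -> ScenarioSet:
    """Sample a ScenarioSet for ``config``.

    ``seed`` overrides ``config.seed``; identical seeds give bit-identical
    arrays.
    """
    seed = config.seed if seed is None else seed
    K, T, S = config.n_hospitals, config.horizon_days, config.n_scenarios
    master = np.random.SeedSequence(seed)
    children = master.spawn(K + 1)
    demand = np.empty((K, T, S), dtype=np.int64)
    for k, hospital in enumerate(config.hospitals):
        demand[k] = _sample(np.random.default_rng(children[k]), hospital.demand, (T, S))
    supply = _sample(
        np.random.default_rng(children[K]), config.blood_center.supply, (T, S)
    )
    return ScenarioSet(
        demand=demand,
        supply=supply,
        probabilities=np.full(S, 1.0 / S),
        seed=seed,
    )


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def apply_cv_setting(config: NetworkConfig, cv: float) -> NetworkConfig:
    """Return a copy of ``config`` with every sd set to ``round(cv * mean)``.

    Rounding is half-up to whole units (0.1 x 225 -> 23). The coefficient
    of variation is recomputed from the mean each time, so applying the
    same ``cv`` twice is idempotent. Means are unchanged.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    hospitals = [
        h.model_copy(
            update={
                "demand": DistributionSpec(
                    mean=h.demand.mean, sd=_round_half_up(cv * h.demand.mean)
                )
            }
        )
        for h in config.hospitals
    ]
    bc = config.blood_center
    blood_center = bc.model_copy(
        update={
            "supply": DistributionSpec(
                mean=bc.supply.mean, sd=_round_half_up(cv * bc.supply.mean)
            )
        }
    )
    return config.model_copy(
        update={"hospitals": hospitals, "blood_center": blood_center}
    )
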