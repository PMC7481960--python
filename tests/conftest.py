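import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from platchain import (
    BloodCenterConfig,
    CostParams,
    DistributionSpec,
    EntityCosts,
    HospitalConfig,
    NetworkConfig,
    base_case_config,
    build_model,
    generate_scenarios,
    solve_model,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


HOSPITAL_COSTS = dict(
    fixed_operating=0.0,
    fixed_shipping=113.0,
    purchase=650.0,
    holding=130.0,
    shortage=3250.0,
    outdating=650.0,
)
CENTER_COSTS = dict(
    fixed_operating=0.0,
    fixed_shipping=1125.0,
    purchase=538.0,
    holding=108.0,
    shortage=2690.0,
    outdating=538.0,
)


def make_config(
    *,
    n_hospitals=1,
    horizon_days=6,
    n_scenarios=1,
    seed=0,
    lead_times=None,
    review_periods=None,
    demand=((10.0, 3.0),),
    supply=(12.0, 4.0),
    center_lead_time=1,
    hospital_ini=None,
    center_ini=None,
    hospital_costs=None,
    center_costs=None,
    supply_pipeline="primed",
) -> NetworkConfig:
    """Small-instance factory with overridable pieces."""
    lead_times = lead_times or [1] * n_hospitals
    review_periods = review_periods or [1] * n_hospitals
    hospital_ini = hospital_ini or [{} for _ in range(n_hospitals)]
    h_costs = EntityCosts(**(hospital_costs or HOSPITAL_COSTS))
    hospitals = [
        HospitalConfig(
            id=k + 1,
            lead_time_days=lead_times[k],
            review_period_days=review_periods[k],
            initial_inventory=hospital_ini[k],
            demand=DistributionSpec(
                mean=demand[k % len(demand)][0], sd=demand[k % len(demand)][1]
            ),
        )
        for k in range(n_hospitals)
    ]
    return NetworkConfig(
        hospitals=hospitals,
        blood_center=BloodCenterConfig(
            lead_time_days=center_lead_time,
            review_period_days=1,
            initial_inventory=center_ini or {},
            supply=DistributionSpec(mean=supply[0], sd=supply[1]),
        ),
        costs=CostParams(
            hospitals=[h_costs] * n_hospitals,
            blood_center=EntityCosts(**(center_costs or CENTER_COSTS)),
        ),
        horizon_days=horizon_days,
        n_scenarios=n_scenarios,
        seed=seed,
        supply_pipeline=supply_pipeline,
    )


@pytest.fixture(scope="session")
def small_base():
    """A 10-day, 2-scenario base-family instance solved to optimality."""
    cfg = base_case_config(horizon_days=10, n_scenarios=2, seed=42)
    sc = generate_scenarios(cfg)
    sol = solve_model(build_model(cfg, sc), mip_rel_gap=0.0)
    return cfg, sc, sol


def random_small_config(rng: np.random.Generator) -> NetworkConfig:
    """Randomized tiny instance for oracle-equivalence sweeps."""
    K = int(rng.integers(1, 3))
    T = int(rng.integers(4, 11))
    lt_bc = int(rng.integers(1, 4))
    T = max(T, lt_bc)
    means = [(float(rng.integers(5, 30)), float(rng.integers(0, 8))) for _ in range(K)]
    return make_config(
        n_hospitals=K,
        horizon_days=T,
        n_scenarios=int(rng.integers(1, 4)),
        seed=int(rng.integers(1 << 16)),
        lead_times=[int(rng.integers(0, 3)) for _ in range(K)],
        review_periods=[int(rng.integers(1, 4)) for _ in range(K)],
        demand=tuple(means),
        supply=(float(rng.integers(5, 40)), float(rng.integers(0, 10))),
        center_lead_time=lt_bc,
        hospital_ini=[
            {2: int(rng.integers(0, 20))} if rng.random() < 0.7 else {}
            for _ in range(K)
        ],
        center_ini={2: int(rng.integers(0, 25))} if rng.random() < 0.5 else {},
        supply_pipeline="primed" if rng.random() < 0.5 else "cold",
    )
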