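# Methods

## The model

`platchain` plans platelet inventory for a two-echelon blood supply chain:
one blood center supplying `K` hospitals over a horizon of `T` days.
Platelets carry a remaining shelf life `l ∈ {1, 2, 3}` days at the point of
distribution; an age-1 unit expires at the end of the day if unused.
Daily hospital demand `D_k,t` and the center's daily raw supply `SUP_t`
are independent draws from per-entity normal distributions, truncated at
zero and rounded to whole units.

Decisions split into two stages:

* **first stage** (identical across scenarios — fixed before any demand or
  supply realizes): each hospital's regular order quantity per day
  `ORHP_k,t`, and the center's age composition of the shipment covering
  that order, `BCTHP_k,t,l`. Orders may be placed only on review days
  (every `RPHP_k` days) and a shipment of age `l` survives the transit
  only if `l > LTHP_k`, so hospitals with longer lead times can receive
  only older-capable (fresher) stock. A binary indicator per delivery
  carries the fixed shipping charge through a big-M link.
* **second stage** (per scenario): FIFO issuing cascades at the hospitals
  (remaining demand / leftover stock per age), the center's regular and
  emergency fulfillment cascades, expiry, and overnight aging.

The objective is the scenario-probability-weighted total of eleven cost
components: fixed operating, fixed shipping, purchasing, holding, shortage
and outdating at each hospital; and fixed operating, fixed shipping,
holding, shortage and outdating at the center. The center's processing
cost per unit is configured but deliberately excluded from the objective:
it is recovered through the hospitals' purchase price.

Unmet hospital demand is not lost: it becomes a same-day emergency order
priced at the hospital's shortage coefficient (an emergency-procurement
price, well above the regular purchase price). The center serves
emergencies from whatever stock remains after regular fulfillment, oldest
first; the residual is procured outside the network. The center's own
shortage coefficient prices the units it must buy externally to cover
**regular** orders that exceed its fresh arrivals. The emergency residual
is *not* charged again at the center — the hospital's emergency price
already pays for those units. This accounting (rather than pricing the
Eq.-28-style total of regular plus emergency shortfalls) is the only one
consistent with the source tables this package reproduces: with mean
demands 200 + 100 against mean supply 225, the network runs a structural
deficit of ~75 units/day, and only the regular-external component (~41
units/day at the optimum) reconciles with the published center shortage
and cost figures. `build_model(price_emergency_shortage=True)` switches
to the alternative pricing for comparison.

### Derived quantities are not variables

Several symbols of the written formulation are pinned by identities and
never reach the solver: the center's procurement equals the day's donor
supply; its fresh arrivals equal procurement one testing lead time
earlier; hospital receipts equal center shipments one transit lead time
earlier (ages shifted); opening inventories are the previous day's
leftovers one age younger; the center's shipment indicator follows from
its arrival stream. After substitution the model holds roughly
`23·T·S + 7·K·T` genuinely free integer variables — about 28,000 at the
reduced experiment scale rather than the millions a literal transcription
produces.

## FIFO, complementarity, and the strict modes

Each cascade stage linearizes `remaining = max(0, in − stock)` as a
difference of two nonnegative variables, `in − stock = remaining − kept`.
Strictly positive holding, shortage and outdating prices force the
complementarity `remaining × kept = 0` at optimality *for most stages*,
but two deviation families are genuinely profitable to a cost minimizer:

* **early discard** — a hospital (or the center's emergency stage 1) can
  expire doomed stock a day before it must, paying the same outdating
  charge but saving a night of holding;
* **stock fabrication / hoarding** — with the emergency residual unpriced,
  a center could keep fresh stock while declaring emergencies unserved
  (or pre-buy externally against a committed aged shipment), banking
  inventory the event rules would have issued.

Always-on valid cuts close the fabrication loopholes exactly
(remaining demand is bounded by the day's demand and monotone along the
cascade; post-emergency leftovers never exceed post-regular leftovers).
The remaining deviations are governed by `strict_fifo`:

* `"full"` — one indicator binary per cascade stage, day and scenario;
  the optimum is exactly event-consistent, and replaying its first stage
  through the simulator reproduces the objective to machine precision.
  Used for small instances, oracle tests and audits.
* `"stock"` (the production default in `optimize`) — indicators only on
  the emergency stages that could hoard center stock. The solved first
  stage is replayable in practice; the replayed cost exceeds the solver
  objective only by the value of early discards.
* `"off"` — cuts only; fastest, and a valid lower bound.

`optimize()` packages the production path: solve `"stock"`, replay the
first stage (which canonicalizes the second stage), and report the exact
replayed cost together with the solver's bound. The certificate
`(objective − lower_bound)/objective` is typically 1e-5–3e-3 on the
experiment instances — tighter than the solver's own gap setting. If a
pathological parameter corner makes the `"stock"` plan physically
unexecutable, `optimize` transparently re-solves in `"full"` mode.

## The event simulator

`simulate.py` replays the daily sequences directly — open, receive,
serve oldest-first, expire, age — with no algebra shared with the model
builder, and prices each entity-day. It is the package's independent
oracle (model vs. replay is a genuine dual route), the canonicalizer of
solver output, and a standalone policy evaluator (`mode="policy"` lets
the center allocate greedily instead of following a stated plan). When
emergency stock is scarce it is split across hospitals pro rata by
emergency size with largest-remainder rounding — the tie-break is a
package choice; the source events name no priority.

## Synthetic data: what it does and does not emulate

`generate_scenarios` draws i.i.d. truncated-rounded normals per entity
from one seeded generator per entity (spawned from the master seed in
entity order, so extending the network never reshuffles existing
entities' draws). Scenario probabilities are uniform `1/S`. The defaults
are the base study conditions: demands `N(200, 32)` and `N(100, 16)`,
supply `N(225, 36)`, lead times (1, 2) days at the hospitals and 5 days
at the center, daily review everywhere, and the cost table
(113/225 fixed shipping, 650 purchase, 130 holding, 3250 shortage,
650 outdating per hospital; 1125/538/108/2690/538 at the center; fixed
operating defaults to 0 because the source tables give it no value).

What this generator does **not** emulate about real platelet logistics:
day-of-week and seasonal demand cycles, correlation between hospitals or
between demand and supply, overdispersion (counts are near-normal, not
negative-binomial), lost or cancelled orders, and multi-product
substitution. Passing tests therefore show that the optimizer and its
accounting are correct under the stated stochastic model, not that the
policy is optimal for any particular real blood system.

## Initial conditions

Initial inventories are inputs; the default gives each entity one mean
day of throughput at two days of remaining life — the stock a
daily-ordering entity carries into a typical day. The center's arrival
stream for days `1..LTBC` is undefined by the in-horizon dynamics (those
orders predate day 1). The default configuration primes it with
pre-horizon procurement at the supply mean (`supply_pipeline="primed"`);
`"cold"` leaves those days empty. Priming matters at reduced horizons: a
cold start leaves the center unsupplied for the first five days, which is
noise at `T=300` (<2%) but biases every KPI upward by ~8% at `T=60`. The
primed default is the steady-state-faithful reading at the scales this
package runs at.

Orders whose delivery would land after the horizon are fixed to zero
(they could only add cost), and end-of-horizon leftovers carry no
holding charge — both standard finite-horizon truncations.

## Reporting conventions

All computation is in raw dollars. Cost *tables* (and the acceptance
report) divide by 100 — the scale on which the reference tables print
their cost figures (their fixed-cost rows equal the fixed shipping
coefficients divided by 100, and entity totals only reconcile with the
cost coefficients under the same factor). Unit KPIs are reported as
plain units/day averaged over days and scenarios; the scenario-cost
summary reports the probability-weighted mean, minimum, maximum and
population standard deviation of per-scenario daily cost. The center's
headline "shortage" KPI counts external procurement for regular orders
(the priced quantity); the total including the emergency residual is
reported alongside as `shortage_total`.

The CV sweep recomputes every standard deviation as `round(cv × mean)`
(half-up). The published grid prints 115 for the center at CV = 0.5 where
no rounding of 112.5 lands; the sweep uses 113 and the difference is far
below sampling noise.

## Problem sizes and solver settings

Experiments run at `T=60` days × `S=20` scenarios with three scenario
seeds per condition — the package's reduced scale, chosen so a full
base-case run certifies within ~0.1% in tens of seconds on one CPU
(`--full-scale` switches the CLI to `T=300, S=100`). The solver is HiGHS
through `scipy.optimize.milp`, single-threaded and deterministic for a
fixed model; default relative gap 1e-3, with an optional wall-clock
limit under which the incumbent is kept and the certificate reports how
far it could be from optimal. Halving the hospital shortage price
(cost-grid row CSET8) makes the instance markedly harder for the solver
— cheap shortages create wide near-ties between ordering and shorting —
and that row runs with a looser gap and a longer limit; its acceptance
check is directional, so the looser certificate is immaterial.

## Rolling horizon

The rolling driver re-solves a `window_days` model, implements the first
`implement_days` of its first stage on one held-out realized path,
advances the simulator, and repeats. Re-solves see fresh scenario draws
(forecast updates) plus the true mid-stream state: current inventories,
supply already in testing, shipments in transit. A plan's aged shipment
can exceed realized stock (the realization is not one of the forecast
scenarios); the driver's recourse substitutes fresh externally procured
units at the center's shortage price — deterministic and priced, so the
realized cost of the concatenated policy is exactly reproducible by
replay (`repair_shipments=True`).

## Known limitations

* Single blood product and blood type; no inter-hospital transshipment
  (the network is a strict hub-and-spoke by regulation).
* Nonanticipativity is all-or-nothing: the whole horizon's orders are
  first-stage. Real planners re-solve weekly — the rolling driver is the
  honest evaluation of that practice.
* The `"stock"` production mode certifies rather than guarantees exact
  event-consistency of the *solver* solution; all reported quantities
  come from the canonical replay, so the reported policy and cost are
  always event-consistent, with the certificate bounding suboptimality.
* The scenario-average model optimizes expected cost only; no risk
  measure (CVaR, chance constraints) is implemented.
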