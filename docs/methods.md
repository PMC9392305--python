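# Methods

## The model

`bedflex` simulates patient flow along a pathway of inpatient units (wards)
arranged as a directed acyclic graph from a single entry unit to a set of
unbounded community destinations. The motivating application is a
centralised acute stroke pathway — a hyper-acute stroke unit (HASU) feeding
one or two acute stroke units (ASUs) and two rehabilitation wards, with
discharge-to-assess community services (P0/P1/P1+/P3) and home as sinks —
but nothing in the engine is stroke-specific.

Each unit has a two-tier capacity: an *allocated* bed base (routinely
staffed and dedicated to the pathway) plus *flex* beds available at short
notice on top of it. The sum is a hard occupancy ceiling; flex beds are
assumed to be instantly available whenever needed, so results represent the
best case for flexible capacity use. The question the model answers is not
"how many beds for a target service level" but "given this allocated + flex
split, how often and by how much must the unit reach beyond its allocated
base" — the flex-capacity requirement that a deterministic averages-based
calculation (arrival rate × mean LOS / target occupancy) cannot see.

Patient dynamics:

* **Arrivals** form a homogeneous Poisson process at the entry unit with
  rate `base_rate × growth_factor` per day. Each arrival is independently a
  *mimic* (a suspected stroke with another diagnosis; short fixed stay,
  discharged home) with probability `mimic_fraction`, otherwise a stroke.
  Diurnal/seasonal cyclicality is deliberately not modelled.
* **Length of stay** (time to discharge readiness) is sampled per unit and
  patient class from a distribution specified by `(family, mean, cv)` —
  exponential, lognormal, gamma or fixed — with native parameters solved
  from the two moments.
* **Routing** is drawn once, at readiness, from the per-class route table.
  If the chosen route carries a fixed post-readiness delay (e.g. awaiting a
  care-home placement), the patient serves it *in their current bed* before
  any destination-capacity check; this is what lets community discharge
  delays propagate pressure upstream.
* **Blocking after service**: a patient routed to a downstream unit that is
  full keeps their bed until space appears. Freed beds pull: first the
  longest-waiting blocked patient destined for the unit, then (at the entry
  unit) the longest-waiting queued arrival; pulls cascade upstream until no
  further move is possible.
* **Entry policy**: arrivals finding the entry unit at its full
  allocated+flex ceiling join an unbounded FIFO queue (default, `wait`), or
  are turned away (`loss`), the latter existing to realise classical loss
  systems for validation.

## The three-phase scheduler

Events are executed by the three-phase method: (A) advance the clock to the
next unconditional event time; (B) execute all unconditional events at that
time — arrivals, discharge readiness, delay expiries; (C) repeatedly fire
conditional events (admissions, transfers) until none applies. Simultaneous
events execute readiness, then delay-expiry, then arrivals, and within a
kind in patient-id order; this favourable-to-patient convention means a bed
freed at time *t* can admit a patient arriving at exactly *t*. The ordering
is fixed so replay is deterministic.

## Random-number discipline

Every replication draws from named substreams keyed by
`(base_seed, replication_index, purpose)` through `numpy` `SeedSequence`,
one substream per purpose and unit (arrival timing, patient classification,
per-unit-and-class LOS, per-unit routing). Per-patient draws are indexed by
patient id rather than consumed in simulation order, so patient *i*'s LOS
at unit *u* is a fixed function of the seed. Consequences: replications are
individually reproducible; consuming more draws at one unit never perturbs
another; and scenario comparisons run under common random numbers with
genuinely coupled sample paths, which the monotonicity tests exploit and
which removes most Monte-Carlo noise from scenario *differences*.

Coupling caveat: under common random numbers, adding flex beds never
lengthens any individual patient's entry wait, and never increases total
blocking time — but an individual patient's own blocking duration can
increase (being admitted earlier, they can meet a full downstream unit at a
different epoch). The test suite asserts exactly the guaranteed forms.

## Measures

Occupancy is analysed as a piecewise-constant function of continuous time
(exact for an event-driven trace), over the results window
`(warmup, warmup + horizon]` only. Per unit: mean total occupancy (beds);
% time within allocated capacity (occupancy = allocated counts as within,
since flex is defined as beds *in addition*); mean flex capacity required,
Σ_{k>allocated} (k − allocated) P(k); % time at the full allocated+flex
ceiling; and the full time-in-state histogram. At entry: the % of arrivals
that found no free bed and had to wait, and the mean wait among them.
Cross-replication aggregation pools time (equal to the mean of
per-replication values for equal windows); standard errors come from
between-replication variance. With Poisson arrivals, the fraction of
arrivals finding the entry unit full equals the time-average probability of
being full (PASTA), which ties the arrival-facing and occupancy-facing
measures together; the suite verifies this on every validation config.

## Validation oracles

The engine is validated against independent exact references rather than
face validity alone:

* **Erlang loss / truncated Poisson**: a single unit under the `loss`
  policy at offered load a = λ·E[LOS] must reproduce Erlang-B blocking
  (stable recurrence B(c) = aB(c−1)/(c + aB(c−1))) and the truncated-Poisson
  occupancy — for *any* LOS family with that mean (insensitivity), which
  checks the non-exponential samplers too.
* **Exact tandem CTMC**: for two exponential units with
  blocking-after-service, the generator of the chain over states
  (queue, serving, blocked, downstream occupancy) is built explicitly and
  the stationary distribution obtained by linear solve; simulated
  time-in-state histograms must agree within 3 Monte-Carlo SE. A capped
  queue variant covers the `wait` policy (the cap is chosen so truncated
  mass is negligible at the tested load).
* **M/M/c/K birth–death** closed form for single-unit queues.
* **Hand-traced fixtures**: two deterministic scenarios with injected
  arrival streams — a 1-bed ward where the second arrival waits exactly
  1.0 day, and a 2-bed→1-bed tandem where the second patient is ready at
  t = 1.5 and blocked for exactly 2.5 days — are asserted event-by-event
  and byte-stable across runs.
* **Little's law**: time-averaged occupancy = admission rate × mean
  admission-to-release time, within 2%.

## Shipped configurations and what they do (and do not) show

`configs/option1.yaml` and `configs/option2.yaml` describe the two
centralised-pathway layouts (one vs two ASUs) with the published capacities
(HASU 22+10; ASU 22+10, or ASU1 15+17 and ASU2 9+11; Rehab 30+5 and 12+5),
the published baseline fixed delays (1.5 days to P3, 0.25 days to P0/P1/P1+),
the 1-day fixed mimic LOS, and the replication protocol (1500 replications,
one-year window, 100-day warm-up). The remaining parameters are
**illustrative**: the original unit-level assumptions are not public, so
arrival volume is anchored on ~1,400 stroke admissions/year uplifted by 5%
projected growth with a 30% mimic fraction, and LOS means are back-derived
once via Little's law from the published mean unit occupancies (20.3, 18.9,
24.4, 9.9 beds), with cv values (0.85–0.9 lognormal for acute stays, 0.8
gamma for rehabilitation) chosen as typical of inpatient LOS data. Mean
occupancies therefore match the published figures essentially by
construction; the distribution-shape measures (% time within allocated,
flex requirement, % time at full) are genuine model outputs and land close
to, but not exactly on, the published values — they depend on the
unpublished distribution shapes. The no-flex variants and the sensitivity
grids (P3 delay, P0/1 delay, mimic LOS, combined system-pressure scenario
with rehab flex cut to 2) reproduce the published sensitivity design.

## Numerical and protocol choices

* Time is continuous, in days; no slotting.
* Warm-up runs from t = 0 with statistics on `(warmup, warmup+horizon]`;
  with `warmup = 0` the window is closed on the left so a t = 0 arrival
  counts. Defaults: 1500 replications, 365-day horizon, 100-day warm-up.
* LOS sampling is by inverse CDF (vectorised in blocks), so fixed stays are
  exact and coupled paths survive capacity changes.
* Waits for patients still queued at the end of a run are not included in
  the mean-delay statistic (right-censored); they still count as delayed.
* Route probabilities must sum to 1 within 1e-9 per unit and class;
  histogram mass checks use the same tolerance.
* The exact-CTMC helper refuses state spaces above 2·10⁴ states.
* Validation protocol sizes: the oracle-equivalence runs use the full 1500
  replications × 365 days (the instances are small); the Option-1-scale
  pipeline checks run at 150–300 replications, where the standard error of
  a mean unit occupancy is already below 0.05 beds.

## Known limitations

* Homogeneous Poisson arrivals: no time-of-day or seasonal cyclicality.
* Flex beds are always available instantly; no staffing, rota or quality
  effects; no inter-hospital travel times; no patient outcomes.
* Community sinks are unbounded — community pressure is represented only
  through route fixed delays.
* Patients never renege from the entry queue, and no diversion is modelled.
* Whether the discharge destination should be drawn at admission instead of
  at readiness is an open modelling choice; readiness-draw is implemented
  (simplest consistent with blocking-after-service; under fixed routing
  probabilities the stationary flows coincide).
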