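# Centralised pathway, Option 1: one hyper-acute stroke unit (HASU), one
# acute stroke unit (ASU), two rehabilitation wards, discharge-to-assess
# community sinks (P0/P1/P1+/P3) plus home.
#
# ILLUSTRATIVE parameters. The unit-level assumptions of the original study
# (LOS families/means, routing fractions, mimic fraction) are not public;
# the values below are plausible stand-ins, not transcriptions. Arrival
# volume is anchored on ~1,400 stroke admissions/year uplifted by 5% projected
# growth; LOS means are back-derived once, via Little's law, from the study's
# published mean unit occupancies (20.3, 18.9, 24.4 and 9.9 beds); cv values,
# the 30% mimic fraction and the routing split are field-plausible choices.
# Capacities, fixed transfer delays (P3: 1.5 days; P0/P1/P1+: 0.25 days) and
# the 1-day mimic LOS are the published baseline values.
name: option1

arrivals:
  base_rate: 5.4795      # suspected-stroke presentations/day = (1400/365)/0.70
  growth_factor: 1.05    # projected growth in suspected stroke conveyances
  mimic_fraction: 0.30
  entry_unit: HASU
  entry_policy: wait

sinks: [P0, P1, P1plus, P3, home]

units:
  - name: HASU
    allocated_beds: 22
    flex_beds: 10
    los:
      stroke: {family: lognormal, mean: 4.6, cv: 0.85}
      mimic: {family: fixed, mean: 1.0}
    routes:
      stroke:
        - {destination: ASU, probability: 0.85, fixed_delay: 0.0}
        - {destination: home, probability: 0.15, fixed_delay: 0.0}
      mimic:
        - {destination: home, probability: 1.0, fixed_delay: 0.0}

  - name: ASU
    allocated_beds: 22
    flex_beds: 10
    los:
      stroke: {family: lognormal, mean: 5.5, cv: 0.9}
    routes:
      stroke:
        - {destination: Rehab 1, probability: 0.30, fixed_delay: 0.0}
        - {destination: Rehab 2, probability: 0.12, fixed_delay: 0.0}
        - {destination: home, probability: 0.58, fixed_delay: 0.0}

  - name: Rehab 1
    allocated_beds: 30
    flex_beds: 5
    los:
      stroke: {family: gamma, mean: 23.2, cv: 0.8}
    routes:
      stroke:
        - {destination: P0, probability: 0.30, fixed_delay: 0.25}
        - {destination: P1, probability: 0.30, fixed_delay: 0.25}
        - {destination: P1plus, probability: 0.15, fixed_delay: 0.25}
        - {destination: P3, probability: 0.25, fixed_delay: 1.5}

  - name: Rehab 2
    allocated_beds: 12
    flex_beds: 5
    los:
      stroke: {family: gamma, mean: 23.5, cv: 0.8}
    routes:
      stroke:
        - {destination: P0, probability: 0.30, fixed_delay: 0.25}
        - {destination: P1, probability: 0.30, fixed_delay: 0.25}
        - {destination: P1plus, probability: 0.15, fixed_delay: 0.25}
        - {destination: P3, probability: 0.25, fixed_delay: 1.5}

settings:
  replications: 1500
  horizon: 365
  warmup: 100
  base_seed: 1
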