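# Option 1 with no flex capacity anywhere on the pathway: every unit is
# capped at its allocated bed base. Derived from option1.yaml.
name: no_flex_anywhere
arrivals:
  base_rate: 5.4795
  growth_factor: 1.05
  mimic_fraction: 0.3
  entry_unit: HASU
  entry_policy: wait
sinks:
- P0
- P1
- P1plus
- P3
- home
units:
- name: HASU
  allocated_beds: 22
  flex_beds: 0
  los:
    stroke:
      family: lognormal
      mean: 4.6
      cv: 0.85
    mimic:
      family: fixed
      mean: 1.0
  routes:
    stroke:
    - destination: ASU
      probability: 0.85
      fixed_delay: 0.0
    - destination: home
      probability: 0.15
      fixed_delay: 0.0
    mimic:
    - destination: home
      probability: 1.0
      fixed_delay: 0.0
- name: ASU
  allocated_beds: 22
  flex_beds: 0
  los:
    stroke:
      family: lognormal
      mean: 5.5
      cv: 0.9
  routes:
    stroke:
    - destination: Rehab 1
      probability: 0.3
      fixed_delay: 0.0
    - destination: Rehab 2
      probability: 0.12
      fixed_delay: 0.0
    - destination: home
      probability: 0.58
      fixed_delay: 0.0
- name: Rehab 1
  allocated_beds: 30
  flex_beds: 0
  los:
    stroke:
      family: gamma
      mean: 23.2
      cv: 0.8
  routes:
    stroke:
    - destination: P0
      probability: 0.3
      fixed_delay: 0.25
    - destination: P1
      probability: 0.3
      fixed_delay: 0.25
    - destination: P1plus
      probability: 0.15
      fixed_delay: 0.25
    - destination: P3
      probability: 0.25
      fixed_delay: 1.5
- name: Rehab 2
  allocated_beds: 12
  flex_beds: 0
  los:
    stroke:
      family: gamma
      mean: 23.5
      cv: 0.8
  routes:
    stroke:
    - destination: P0
      probability: 0.3
      fixed_delay: 0.25
    - destination: P1
      probability: 0.3
      fixed_delay: 0.25
    - destination: P1plus
      probability: 0.15
      fixed_delay: 0.25
    - destination: P3
      probability: 0.25
      fixed_delay: 1.5
settings:
  replications: 1500
  horizon: 365
  warmup: 100
  base_seed: 1
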