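# Variations to the fixed delay from the rehabilitation wards to the
# home-based D2A P0/P1/P1+ services. Baseline = 0.25 days.
# Run against configs/option1.yaml.
grid:
  - name: p01_delay_0.25_baseline
    overrides: []
  - name: p01_delay_0.5
    overrides:
      - {path: [units, Rehab 1, routes, stroke, P0, fixed_delay], value: 0.5}
      - {path: [units, Rehab 1, routes, stroke, P1, fixed_delay], value: 0.5}
      - {path: [units, Rehab 1, routes, stroke, P1plus, fixed_delay], value: 0.5}
      - {path: [units, Rehab 2, routes, stroke, P0, fixed_delay], value: 0.5}
      - {path: [units, Rehab 2, routes, stroke, P1, fixed_delay], value: 0.5}
      - {path: [units, Rehab 2, routes, stroke, P1plus, fixed_delay], value: 0.5}
  - name: p01_delay_1.0
    overrides:
      - {path: [units, Rehab 1, routes, stroke, P0, fixed_delay], value: 1.0}
      - {path: [units, Rehab 1, routes, stroke, P1, fixed_delay], value: 1.0}
      - {path: [units, Rehab 1, routes, stroke, P1plus, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P0, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P1, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P1plus, fixed_delay], value: 1.0}
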