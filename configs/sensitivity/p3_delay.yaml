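# Variations to the fixed delay from the rehabilitation wards to the
# bedded D2A P3 (care home) service. Baseline = 1.5 days.
# Run against configs/option1.yaml.
grid:
  - name: p3_delay_1.0
    overrides:
      - {path: [units, Rehab 1, routes, stroke, P3, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P3, fixed_delay], value: 1.0}
  - name: p3_delay_1.5_baseline
    overrides: []
  - name: p3_delay_2.0
    overrides:
      - {path: [units, Rehab 1, routes, stroke, P3, fixed_delay], value: 2.0}
      - {path: [units, Rehab 2, routes, stroke, P3, fixed_delay], value: 2.0}
  - name: p3_delay_3.0
    overrides:
      - {path: [units, Rehab 1, routes, stroke, P3, fixed_delay], value: 3.0}
      - {path: [units, Rehab 2, routes, stroke, P3, fixed_delay], value: 3.0}
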