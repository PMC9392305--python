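# Combined system-pressure scenario: 3-day fixed delay from the rehab wards
# to the D2A P3 service (baseline 1.5), 2-day HASU mimic LOS (baseline 1),
# 1-day fixed delay from the rehab wards to the D2A P0/P1/P1+ services
# (baseline 0.25), and only 2 flex beds at each rehab ward (baseline 5).
# Run against configs/option1.yaml.
grid:
  - name: baseline
    overrides: []
  - name: system_pressure
    overrides:
      - {path: [units, Rehab 1, routes, stroke, P3, fixed_delay], value: 3.0}
      - {path: [units, Rehab 2, routes, stroke, P3, fixed_delay], value: 3.0}
      - {path: [units, HASU, los, mimic, mean], value: 2.0}
      - {path: [units, Rehab 1, routes, stroke, P0, fixed_delay], value: 1.0}
      - {path: [units, Rehab 1, routes, stroke, P1, fixed_delay], value: 1.0}
      - {path: [units, Rehab 1, routes, stroke, P1plus, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P0, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P1, fixed_delay], value: 1.0}
      - {path: [units, Rehab 2, routes, stroke, P1plus, fixed_delay], value: 1.0}
      - {path: [units, Rehab 1, flex_beds], value: 2}
      - {path: [units, Rehab 2, flex_beds], value: 2}
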