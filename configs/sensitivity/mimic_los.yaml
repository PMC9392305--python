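# Variations to the HASU length of stay assumed for mimic patients.
# Baseline = 1 day (fixed). Run against configs/option1.yaml.
grid:
  - name: mimic_los_0.5
    overrides:
      - {path: [units, HASU, los, mimic, mean], value: 0.5}
  - name: mimic_los_1.0_baseline
    overrides: []
  - name: mimic_los_2.0
    overrides:
      - {path: [units, HASU, los, mimic, mean], value: 2.0}
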