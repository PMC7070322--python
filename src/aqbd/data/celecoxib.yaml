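schema_version: 1

# Celecoxib impurity-method optimization study: three critical method
# parameters, four critical method attributes.
factors:
  - {name: acetonitrile, unit: "% (v/v)", low: 42, high: 50}
  - {name: flow_rate, unit: "mL/min", low: 0.5, high: 1.0}
  - {name: temperature, unit: "degC", low: 30, high: 40}

responses:
  - {name: R1}   # resolution EP impurity A / celecoxib
  - {name: R2}   # resolution celecoxib / USP related compound C
  - {name: R3}   # resolution USP related compound C / D
  - {name: RT, unit: "min"}  # retention time of EP impurity B

cmas:
  - {response: R1, direction: not_less_than, limit: 2.3}
  - {response: R2, direction: not_less_than, limit: 3.2}
  - {response: R3, direction: not_less_than, limit: 2.0}
  - {response: RT, direction: not_more_than, limit: 45}

design:
  kind: ccf
  n_center: 3

model:
  alpha: 0.05

modr:
  grid:
    axes:
      - {name: acetonitrile, low: 42, high: 50, n_points: 101}
      - {name: flow_rate, low: 0.5, high: 1.0, n_points: 101}
    fixed: {temperature: 40}
  n_simulations: 10000
  seed: 20200813
  assurance_level: 0.99
  include_residual: true
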