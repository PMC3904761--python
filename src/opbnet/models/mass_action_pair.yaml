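format_version: '1'
metadata:
  name: mass_action_pair
  description: Reversible mass-action pair A <-> B (chemical domain)
entities:
- id: pool_a
  label: Species pool A
  domain: chemical
- id: pool_b
  label: Species pool B
  domain: chemical
properties:
- id: amount_a
  class: chemical.amount
  bearer: pool_a
  label: Amount of A
  unit: mol
  value: 1.0
- id: amount_b
  class: chemical.amount
  bearer: pool_b
  label: Amount of B
  unit: mol
  value: 2.0
- id: flux
  class: chemical.flow
  bearer: pool_a
  label: Net reaction flux
  unit: mol/s
- id: kf
  class: chemical.rate_constant
  bearer: pool_a
  label: Forward rate constant
  unit: (mol/s)/(mol)
  value: 2.0
- id: kr
  class: chemical.rate_constant
  bearer: pool_b
  label: Reverse rate constant
  unit: (mol/s)/(mol)
  value: 1.0
dependencies:
- id: bnd_a
  kind: boundary_flow
  bindings:
  - role: amount_player
    property: amount_a
  - role: outflow
    property: flux
- id: bnd_b
  kind: boundary_flow
  bindings:
  - role: amount_player
    property: amount_b
  - role: inflow
    property: flux
- id: rxn
  kind: mass_action
  bindings:
  - role: flow_player
    property: flux
  - role: source_player
    property: amount_a
  - role: target_player
    property: amount_b
  - role: constitutive
    property: kf
  - role: constitutive
    property: kr
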