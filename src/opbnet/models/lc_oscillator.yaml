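format_version: '1'
metadata:
  name: lc_oscillator
  description: Lossless LC oscillator (electrical domain)
entities:
- id: capacitor
  label: Capacitor
  domain: electrical
- id: inductor
  label: Inductor
  domain: electrical
properties:
- id: cap_force
  class: electrical.force
  bearer: capacitor
  label: Capacitor potential
  unit: V
- id: capacitance
  class: electrical.capacitance
  bearer: capacitor
  label: capacitance
  unit: (C)/(V)
  value: 1.0
- id: charge
  class: electrical.amount
  bearer: capacitor
  label: Capacitor charge
  unit: C
  value: 1.0
- id: current
  class: electrical.flow
  bearer: inductor
  label: Loop current
  unit: A
- id: flux
  class: electrical.momentum
  bearer: inductor
  label: Inductor flux linkage
  unit: Wb
  value: 0.0
- id: inductance
  class: electrical.inductance
  bearer: inductor
  label: inductance
  unit: (Wb)/(A)
  value: 1.0
dependencies:
- id: bnd_flow
  kind: boundary_flow
  bindings:
  - role: amount_player
    property: charge
  - role: outflow
    property: current
- id: bnd_force
  kind: boundary_force
  bindings:
  - role: momentum_player
    property: flux
  - role: force_player_high
    property: cap_force
- id: cap_dep
  kind: capacitive
  bindings:
  - role: amount_player
    property: charge
  - role: force_player
    property: cap_force
  - role: constitutive
    property: capacitance
- id: ind_dep
  kind: inductive
  bindings:
  - role: momentum_player
    property: flux
  - role: flow_player
    property: current
  - role: constitutive
    property: inductance
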