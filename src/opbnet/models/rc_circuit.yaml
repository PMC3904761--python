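format_version: '1'
metadata:
  name: rc_circuit
  description: Series RC charging circuit (electrical domain)
entities:
- id: capacitor
  label: RC element
  domain: electrical
- id: source
  label: Voltage source
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
  value: 0.5
- id: charge
  class: electrical.amount
  bearer: capacitor
  label: Capacitor charge
  unit: C
  value: 0.0
- id: current
  class: electrical.flow
  bearer: capacitor
  label: Charging current
  unit: A
- id: resistance
  class: electrical.resistance
  bearer: capacitor
  label: resistance
  unit: (V)/(A)
  value: 2.0
- id: src_force
  class: electrical.force
  bearer: source
  label: Source potential
  unit: V
dependencies:
- id: bnd_dep
  kind: boundary_flow
  bindings:
  - role: amount_player
    property: charge
  - role: inflow
    property: current
- id: cap_dep
  kind: capacitive
  bindings:
  - role: amount_player
    property: charge
  - role: force_player
    property: cap_force
  - role: constitutive
    property: capacitance
- id: res_dep
  kind: resistive
  bindings:
  - role: force_player_high
    property: src_force
  - role: force_player_low
    property: cap_force
  - role: flow_player
    property: current
  - role: constitutive
    property: resistance
sources:
- property: src_force
  waveform: constant
  level: 1.0
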