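format_version: '1'
metadata:
  name: windkessel
  description: Two-element Windkessel (fluid domain)
entities:
- id: artery
  label: Compliant arterial segment
  domain: fluid
- id: heart
  label: Inflow pump
  domain: fluid
- id: vein
  label: Venous sink
  domain: fluid
properties:
- id: compliance
  class: fluid.capacitance
  bearer: artery
  label: compliance
  unit: (m^3)/(Pa)
  value: 1.0
- id: inflow
  class: fluid.flow
  bearer: heart
  label: Cardiac inflow
  unit: m^3/s
- id: outflow
  class: fluid.flow
  bearer: artery
  label: Peripheral outflow
  unit: m^3/s
- id: pressure
  class: fluid.force
  bearer: artery
  label: Arterial pressure
  unit: Pa
- id: resistance
  class: fluid.resistance
  bearer: artery
  label: resistance
  unit: (Pa)/(m^3/s)
  value: 1.0
- id: venous_pressure
  class: fluid.force
  bearer: vein
  label: Venous pressure
  unit: Pa
- id: volume
  class: fluid.amount
  bearer: artery
  label: Arterial volume
  unit: m^3
  value: 0.0
dependencies:
- id: bnd_dep
  kind: boundary_flow
  bindings:
  - role: amount_player
    property: volume
  - role: inflow
    property: inflow
  - role: outflow
    property: outflow
- id: cap_dep
  kind: capacitive
  bindings:
  - role: amount_player
    property: volume
  - role: force_player
    property: pressure
  - role: constitutive
    property: compliance
- id: res_dep
  kind: resistive
  bindings:
  - role: force_player_high
    property: pressure
  - role: force_player_low
    property: venous_pressure
  - role: flow_player
    property: outflow
  - role: constitutive
    property: resistance
sources:
- property: inflow
  waveform: constant
  level: 1.0
- property: venous_pressure
  waveform: constant
  level: 0.0
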