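format_version: '1'
metadata:
  name: windkessel_discharge
  description: Compliant vessel discharging through a resistance (fluid domain)
entities:
- id: capacitor
  label: RC element
  domain: fluid
- id: source
  label: Voltage source
  domain: fluid
properties:
- id: cap_force
  class: fluid.force
  bearer: capacitor
  label: Capacitor potential
  unit: Pa
- id: capacitance
  class: fluid.capacitance
  bearer: capacitor
  label: capacitance
  unit: (m^3)/(Pa)
  value: 0.5
- id: charge
  class: fluid.amount
  bearer: capacitor
  label: Capacitor charge
  unit: m^3
  value: 1.0
- id: current
  class: fluid.flow
  bearer: capacitor
  label: Charging current
  unit: m^3/s
- id: resistance
  class: fluid.resistance
  bearer: capacitor
  label: resistance
  unit: (Pa)/(m^3/s)
  value: 2.0
- id: src_force
  class: fluid.force
  bearer: source
  label: Source potential
  unit: Pa
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
  level: 0.0
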