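format_version: '1'
metadata:
  name: chemo_mech_transducer
  description: Chemo-mechanical transduction against a viscous load
entities:
- id: anchor
  label: Mechanical anchor
  domain: mechanical
- id: fiber
  label: Contractile fiber
  domain: mechanical
- id: fuel
  label: Chemical fuel pool
  domain: chemical
properties:
- id: anchor_force
  class: mechanical.force
  bearer: anchor
  label: Anchor reference force
  unit: N
- id: drag
  class: mechanical.resistance
  bearer: fiber
  label: Viscous load resistance
  unit: (N)/(m/s)
  value: 1.0
- id: mech_force
  class: mechanical.force
  bearer: fiber
  label: Contractile force
  unit: N
- id: modulus
  class: modulus
  bearer: fiber
  label: Transduction modulus
  unit: '1'
  value: 2.0
- id: molar_flux
  class: chemical.flow
  bearer: fuel
  label: Fuel consumption flux
  unit: mol/s
- id: mu
  class: chemical.force
  bearer: fuel
  label: Chemical potential
  unit: J/mol
- id: velocity
  class: mechanical.flow
  bearer: fiber
  label: Shortening velocity
  unit: m/s
dependencies:
- id: load
  kind: resistive
  bindings:
  - role: force_player_high
    property: mech_force
  - role: force_player_low
    property: anchor_force
  - role: flow_player
    property: velocity
  - role: constitutive
    property: drag
- id: xdc
  kind: transducer
  bindings:
  - role: force_player_1
    property: mu
  - role: flow_player_1
    property: molar_flux
  - role: force_player_2
    property: mech_force
  - role: flow_player_2
    property: velocity
  - role: constitutive
    property: modulus
sources:
- property: anchor_force
  waveform: constant
  level: 0.0
- property: mu
  waveform: constant
  level: 1.0
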