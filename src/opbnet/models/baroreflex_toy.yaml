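format_version: '1'
metadata:
  name: baroreflex_toy
  description: Baroreceptor reflex as a proportional transactor
entities:
- id: aorta
  label: Aortic segment
  domain: fluid
- id: sa_node
  label: Sinoatrial pacemaker
  domain: chemical
properties:
- id: aortic_pressure
  class: fluid.force
  bearer: aorta
  label: Aortic pressure
  unit: Pa
- id: gain
  class: coefficient
  bearer: sa_node
  label: Reflex gain
  unit: '1'
  value: -0.5
- id: heart_rate
  class: chemical.flow
  bearer: sa_node
  label: Heart rate (proxy rate property)
  unit: mol/s
dependencies:
- id: reflex
  kind: transactor
  bindings:
  - role: source_player
    property: aortic_pressure
  - role: target_player
    property: heart_rate
  - role: constitutive
    property: gain
sources:
- property: aortic_pressure
  waveform: constant
  level: 1.0
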