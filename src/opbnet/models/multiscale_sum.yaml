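format_version: '1'
metadata:
  name: multiscale_sum
  description: Summation over proper parts (fluid volumes)
entities:
- id: lobe_1
  label: Lobe 1
  domain: fluid
  part_of: organ
- id: lobe_2
  label: Lobe 2
  domain: fluid
  part_of: organ
- id: lobe_3
  label: Lobe 3
  domain: fluid
  part_of: organ
- id: organ
  label: Whole organ
  domain: fluid
properties:
- id: vol_lobe_1
  class: fluid.amount
  bearer: lobe_1
  label: Lobe 1 volume
  unit: m^3
  value: 1.0
  fixed: true
- id: vol_lobe_2
  class: fluid.amount
  bearer: lobe_2
  label: Lobe 2 volume
  unit: m^3
  value: 2.0
  fixed: true
- id: vol_lobe_3
  class: fluid.amount
  bearer: lobe_3
  label: Lobe 3 volume
  unit: m^3
  value: 3.0
  fixed: true
- id: vol_organ
  class: fluid.amount
  bearer: organ
  label: Organ volume
  unit: m^3
dependencies:
- id: sum_dep
  kind: summation
  bindings:
  - role: whole_player
    property: vol_organ
  - role: part_player
    property: vol_lobe_1
  - role: part_player
    property: vol_lobe_2
  - role: part_player
    property: vol_lobe_3
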