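compartments:
- id: c
  name: cell
  volume: 1.0
groups:
- members:
  - - r1.k
    - 0.1
  name: k1
- members:
  - - r2.k
    - 10.0
  name: k2
metabolites:
- carbons: 0
  compartment: c
  constant: true
  id: A
  initial: 0.5
  labelable: false
  name: ''
- carbons: 0
  compartment: c
  constant: false
  id: B
  initial: 0.005
  labelable: false
  name: ''
- carbons: 0
  compartment: c
  constant: false
  id: C
  initial: 0.0
  labelable: false
  name: ''
name: degenerate_pair
ncell: 1.0
parameters:
  r1.k: 0.1
  r1.keq: 1.0
  r2.k: 10.0
reactions:
- id: r1
  invisible: false
  law:
    args:
      products:
      - B
      substrates:
      - A
    template: reversible_mass_action
  name: ''
  products:
  - - B
    - 1
  reversible: true
  substrates:
  - - A
    - 1
- id: r2
  invisible: false
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - B
        - 1
    template: mass_action
  name: ''
  products:
  - - C
    - 1
  reversible: false
  substrates:
  - - B
    - 1
symmetric: []
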