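compartments:
- id: c
  name: cell
  volume: 1.0
groups:
- members:
  - - r1.k
    - 0.05
  name: k1
- members:
  - - r2.k
    - 0.08
  name: k2
- members:
  - - r3.k
    - 0.06
  name: k3
metabolites:
- carbons: 3
  compartment: c
  constant: true
  id: A
  initial: 1.0
  labelable: true
  name: ''
- carbons: 3
  compartment: c
  constant: false
  id: B
  initial: 0.625
  labelable: true
  name: ''
- carbons: 3
  compartment: c
  constant: false
  id: C
  initial: 0.8333333333333334
  labelable: true
  name: ''
- carbons: 0
  compartment: c
  constant: true
  id: OUT
  initial: 0.0
  labelable: false
  name: ''
name: chain3
ncell: 1.0
parameters:
  r1.k: 0.05
  r2.k: 0.08
  r3.k: 0.06
reactions:
- id: r1
  invisible: false
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - A
        - 1
    template: mass_action
  name: ''
  products:
  - - B
    - 1
  reversible: false
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
- id: r3
  invisible: false
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - C
        - 1
    template: mass_action
  name: ''
  products:
  - - OUT
    - 1
  reversible: false
  substrates:
  - - C
    - 1
symmetric: []
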