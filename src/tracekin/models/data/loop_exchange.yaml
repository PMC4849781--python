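compartments:
- id: c
  name: cell
  volume: 1.0
groups:
- members:
  - - exch.k
    - 0.2
  name: exch
metabolites:
- carbons: 2
  compartment: c
  constant: false
  id: A
  initial: 1.0
  labelable: true
  name: ''
- carbons: 2
  compartment: c
  constant: false
  id: B
  initial: 2.0
  labelable: true
  name: ''
name: loop_exchange
ncell: 1.0
parameters:
  exch.k: 0.2
reactions:
- id: exch
  invisible: true
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - A
        - 1
      - - B
        - 1
    template: mass_action
  name: ''
  products:
  - - A
    - 1
  - - B
    - 1
  reversible: false
  substrates:
  - - A
    - 1
  - - B
    - 1
symmetric: []
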