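compartments:
- id: c
  name: cell
  volume: 1.0
groups:
- members:
  - - feed.k
    - 0.1
  name: feed
- members:
  - - fh.k
    - 0.5
  name: fh
- members:
  - - out.k
    - 0.2
  name: out
metabolites:
- carbons: 4
  compartment: c
  constant: true
  id: SRC
  initial: 1.0
  labelable: true
  name: ''
- carbons: 4
  compartment: c
  constant: false
  id: fum
  initial: 0.5
  labelable: true
  name: ''
- carbons: 4
  compartment: c
  constant: false
  id: mal
  initial: 0.5
  labelable: true
  name: ''
- carbons: 0
  compartment: c
  constant: true
  id: OUT
  initial: 0.0
  labelable: false
  name: ''
name: symmetric_krebs_stub
ncell: 1.0
parameters:
  feed.k: 0.1
  fh.k: 0.5
  out.k: 0.2
reactions:
- id: feed
  invisible: false
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - SRC
        - 1
    template: mass_action
  name: ''
  products:
  - - fum
    - 1
  reversible: false
  substrates:
  - - SRC
    - 1
- id: fh
  invisible: false
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - fum
        - 1
    template: mass_action
  name: ''
  products:
  - - mal
    - 1
  reversible: false
  substrates:
  - - fum
    - 1
- id: out
  invisible: false
  law:
    args:
      products: []
      reversible: false
      substrates:
      - - mal
        - 1
    template: mass_action
  name: ''
  products:
  - - OUT
    - 1
  reversible: false
  substrates:
  - - mal
    - 1
symmetric:
- fum
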