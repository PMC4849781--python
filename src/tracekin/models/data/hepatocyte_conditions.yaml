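conditions:
- id: A1
  initial:
    eFru: 3.0
    eGlc: 20.0
  t_end: 120.0
  tracers:
    eGlc:
    - - 3
      - 0.5
    - - 0
      - 0.5
- id: A2
  initial:
    eFru: 3.0
    eGlc: 20.0
  t_end: 120.0
  tracers:
    eFru:
    - - 63
      - 0.5
    - - 0
      - 0.5
- id: B
  initial:
    eFru: 20.0
    eGlc: 20.0
  t_end: 120.0
  tracers:
    eGlc:
    - - 3
      - 0.5
    - - 0
      - 0.5
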