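# Negation trigger phrases (pre-mention, NegEx-style) and scope-terminating cues.
triggers:
  - no evidencia de
  - no se observa
  - no se evidencia
  - sin evidencia de
  - ausencia de
  - se descarta
  - niega
  - descarta
  - sin
  - "no"
scope_breakers:
  - ","
  - ";"
  - pero
  - aunque
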