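# Concept -> surface patterns (versioned, authored inventory).
# Matching is case/diacritic-insensitive, word-boundary anchored, longest-first.
version: 1
concepts:
  AF:
    - fibrilacion auricular paroxistica
    - fibrilacion auricular persistente
    - fibrilacion auricular permanente
    - fibrilacion auricular
    - ac x fa
    - acxfa
    - fa
  SINUS_RHYTHM:
    - ritmo sinusal normal
    - ritmo sinusal
    - rs
  CARDIOVERSION:
    - cardioversion electrica
    - cardioversion farmacologica
    - cardioversion
    - cve
  ABLATION:
    - ablacion de venas pulmonares
    - ablacion
  HF:
    - insuficiencia cardiaca congestiva
    - insuficiencia cardiaca descompensada
    - insuficiencia cardiaca
    - icc
    - ic
  OTHER_ARRHYTHMIA:
    - flutter auricular
    - flutter
    - taquicardia ventricular
    - taquicardia supraventricular
    - taquicardia auricular
    - tsv
    - tv
    - bloqueo auriculoventricular
    - extrasistoles ventriculares
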