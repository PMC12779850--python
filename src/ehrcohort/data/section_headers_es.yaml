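# Canonical section id -> header surface forms (matched case/diacritic-insensitively
# at line starts, followed by ':'). Text before the first header falls into "otros".
antecedentes:
  - antecedentes personales
  - antecedentes
enfermedad_actual:
  - enfermedad actual
  - motivo de ingreso
  - historia actual
exploracion:
  - exploracion fisica
  - exploracion
evolucion:
  - evolucion clinica
  - evolucion
tratamiento:
  - tratamiento al alta
  - tratamiento
juicio_diagnostico:
  - juicio diagnostico
  - juicio clinico
  - diagnostico principal
ecg:
  - ecg
  - electrocardiograma
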