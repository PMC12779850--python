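# Spanish zero-shot prompt bodies. The leading [[step:...]] tag is a
# machine-readable step marker used by the deterministic test backends; real
# model backends simply ignore it. Slots are filled with str.format.
concatenation: |
  [[step:concatenation]]
  Eres un asistente de documentación clínica. A continuación tienes todos los
  informes de alta de un paciente, ordenados cronológicamente y precedidos por
  su fecha.
  {report_blocks}
  ¿Presenta el paciente progresión de {disease} (recurrencia o permanencia)
  entre 1 mes y 2 años después del episodio inicial? Responde únicamente con
  una de estas etiquetas: {label_set}.
summarization_worker: |
  [[step:summarization_worker]]
  Eres un asistente de documentación clínica. Resumen previo de la historia:
  <<RESUMEN>>
  {summary}
  <<FIN RESUMEN>>
  Nuevo informe de alta:
  {report_block}
  Actualiza el resumen extrayendo solo la información relevante para
  determinar la progresión de {disease}: resultados de electrocardiograma,
  episodios de {disease}, cardioversiones y ablaciones, con sus fechas.
  Devuelve únicamente el resumen actualizado.
summarization_manager: |
  [[step:summarization_manager]]
  Eres un asistente de documentación clínica. Resumen completo de la historia
  clínica del paciente:
  <<RESUMEN>>
  {summary}
  <<FIN RESUMEN>>
  Según este resumen, ¿presenta el paciente progresión de {disease}
  (recurrencia o permanencia) entre 1 mes y 2 años después del episodio
  inicial? Responde únicamente con una de estas etiquetas: {label_set}.
onset_debut: |
  [[step:onset_debut]]
  Eres un asistente de documentación clínica. Lee el siguiente informe de alta.
  {report_block}
  ¿Contiene este informe evidencia del diagnóstico inicial (debut) de
  {disease}? Responde únicamente: Sí o No.
onset_progression: |
  [[step:onset_progression]]
  Eres un asistente de documentación clínica. El debut de {disease} ya ha sido
  identificado.
  {date_fragment}
  {report_block}
  ¿Documenta este informe progresión de {disease} (Sí), retorno a ritmo
  sinusal (No), o ninguna de las dos cosas? Responde únicamente con una de
  estas etiquetas: {label_set}.
chronology_remission: |
  [[step:chronology_remission]]
  Eres un asistente de documentación clínica. Este informe está fechado dentro
  del primer mes tras el debut de {disease}.
  {date_fragment}
  {report_block}
  ¿Documenta este informe un retorno a ritmo sinusal? Responde únicamente:
  Sí o No.
chronology_progression: |
  [[step:chronology_progression]]
  Eres un asistente de documentación clínica. Este informe está fechado entre
  1 mes y 2 años después del debut de {disease}.
  {date_fragment}
  {report_block}
  ¿Documenta este informe progresión de {disease} (Sí), retorno a ritmo
  sinusal (No), o ninguna de las dos cosas? Responde únicamente con una de
  estas etiquetas: {label_set}.
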