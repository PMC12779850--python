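# English zero-shot prompt bodies; slot-compatible with the Spanish set.
# The [[step:...]] tag is a machine-readable marker for deterministic test
# backends; real model backends ignore it.
concatenation: |
  [[step:concatenation]]
  You are a clinical documentation assistant. Below are all the discharge
  reports of one patient, in chronological order, each preceded by its date.
  {report_blocks}
  Does the patient show progression of {disease} (recurrence or permanence)
  between 1 month and 2 years after the initial episode? Answer with exactly
  one of these labels: {label_set}.
summarization_worker: |
  [[step:summarization_worker]]
  You are a clinical documentation assistant. Previous history summary:
  <<RESUMEN>>
  {summary}
  <<FIN RESUMEN>>
  New discharge report:
  {report_block}
  Update the summary, extracting only the information relevant for
  determining {disease} progression: electrocardiogram results, {disease}
  episodes, cardioversion procedures, and ablations, with their dates.
  Return only the updated summary.
summarization_manager: |
  [[step:summarization_manager]]
  You are a clinical documentation assistant. Complete summary of the
  patient's clinical history:
  <<RESUMEN>>
  {summary}
  <<FIN RESUMEN>>
  According to this summary, does the patient show progression of {disease}
  (recurrence or permanence) between 1 month and 2 years after the initial
  episode? Answer with exactly one of these labels: {label_set}.
onset_debut: |
  [[step:onset_debut]]
  You are a clinical documentation assistant. Read the following discharge
  report.
  {report_block}
  Does this report contain evidence of the initial (debut) diagnosis of
  {disease}? Answer only: Yes or No.
onset_progression: |
  [[step:onset_progression]]
  You are a clinical documentation assistant. The {disease} debut has already
  been identified.
  {date_fragment}
  {report_block}
  Does this report document {disease} progression (Yes), a return to sinus
  rhythm (No), or neither? Answer with exactly one of these labels:
  {label_set}.
chronology_remission: |
  [[step:chronology_remission]]
  You are a clinical documentation assistant. This report is dated within the
  first month after the {disease} debut.
  {date_fragment}
  {report_block}
  Does this report document a return to sinus rhythm? Answer only: Yes or No.
chronology_progression: |
  [[step:chronology_progression]]
  You are a clinical documentation assistant. This report is dated between
  1 month and 2 years after the {disease} debut.
  {date_fragment}
  {report_block}
  Does this report document {disease} progression (Yes), a return to sinus
  rhythm (No), or neither? Answer with exactly one of these labels:
  {label_set}.
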