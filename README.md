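# ehrcohort

Cohort selection from longitudinal free-text discharge reports, for clinical
NLP researchers and registry teams who need to decide, per patient, whether an
episodic disease progressed after its first documented episode.

The package targets two concrete phenotypes over Spanish discharge reports:

* **Atrial-fibrillation (AF) progression** — did AF recur or persist between
  1 month and 2 years after the first documented AF episode (the *debut*)?
  A documented return to sinus rhythm from 1 day after the debut, with no
  in-window recurrence, means non-progression. Label set: 1 (progression),
  0 (non-progression), −1 (unknown / insufficient information).
* **Heart-failure (HF) decompensation** — a new HF episode between 1 week and
  2 years after the HF debut (1), a debut with no later episode (0), or no
  documented debut at all (−1).

Both tasks require reasoning across a patient's *whole* report history and
over the temporal relation between events, which is exactly where both
regular-expression systems and large language models tend to fail. The
package implements and instruments both families of approaches:

1. **Rule pipeline** — section segmentation of each report (ANTECEDENTES,
   EVOLUCIÓN, ECG, ...), lexicon-based concept mention extraction
   (case/diacritic-insensitive, word-boundary anchored), NegEx-style
   pre-mention negation detection, and a temporal engine that classifies each
   report against the debut date into `PRE_DEBUT / REMISSION_WINDOW /
   PROGRESSION_WINDOW / POST_WINDOW` and aggregates the per-report evidence
   into the 3-class patient label with a full decision trace.
2. **Prompting strategies** over a pluggable text-model backend
   (`complete(prompt) -> str`, optional per-label log-likelihood scoring):
   *concatenation* of the whole dated history in one call; *summarization*
   (a worker call per report folds it into a running summary, a manager call
   labels the final summary — n+1 calls); *onset-guided* (find the debut,
   then ask a 3-class question per later report with the debut date rendered
   numerically, in words, or as a day offset); and *chronology-guided* (the
   orchestrator itself applies the task windows and never shows the backend a
   report beyond the 2-year bound).

Because real discharge reports are private, the package ships a
**synthetic-cohort generator** that plants affirmed/negated Spanish mentions
of AF, sinus rhythm, cardioversion/ablation, HF and distractor arrhythmias
into sectioned template notes at controlled day offsets, with gold labels
derived from the planted events through the same window arithmetic as the
labeler — plus adversarial cohorts (pure-negation, other-arrhythmia,
two-contrary-ECGs) and deterministic test backends (an oracle that answers
from the planted events, a context-truncating wrapper, and a verbose wrapper
that violates the label-only instruction). Evaluation covers accuracy,
macro-F1 with a separate format-error tally, Cohen's κ, stepwise outcome
taxonomy, a temporality audit, and log-likelihood margin summaries with
manual-review flags.

## Worked example

```python
import ehrcohort as ec

spec = ec.af_progression()
params = ec.default_params(spec, n_patients=200, seed=42, negation_rate=0.2)
cohort = ec.generate_cohort(params, spec)

gold = {p.history.patient_id: p.gold_label for p in cohort}
pred = {pid: ec.label_patient_rule_based(p.history, spec)
        for pid, p in ((p.history.patient_id, p) for p in cohort)}
report = ec.score(pred, gold)
print(f"rule pipeline: accuracy={report.accuracy:.3f} macro_f1={report.macro_f1:.3f}")

oracle = ec.OracleBackend(cohort, spec, margin=4.0)
trunc = ec.TruncatingBackend(oracle, max_chars=900)
onset = {p.history.patient_id: ec.run_onset_guided(p.history, oracle, spec=spec).label
         for p in cohort}
concat = {p.history.patient_id: ec.run_concatenation(p.history, trunc, spec=spec).label
          for p in cohort}
print("onset-guided:", ec.score(onset, gold).accuracy,
      " concatenation (truncated):", ec.score(concat, gold).accuracy)
```

prints

```
rule pipeline:  accuracy=1.000  macro_f1=1.000  format_errors=0
onset-guided (num)         accuracy=1.000  macro_f1=1.000
concatenation (truncated)  accuracy=0.550  macro_f1=0.472
```

On clean synthetic cohorts the rule pipeline and the decomposed strategies
recover the planted gold label exactly; concatenating the whole history
through a fixed context budget loses the later-report evidence and drops to
chance-like accuracy — the long-context failure mode the decomposed
strategies exist to avoid. Each label carries a trace of per-report
decisions (`debut_search`, `remission_check`, `progression_check`, with
window class and day offset) and `ec.review_flags` raises `TEMPORALITY` when
debut and progression evidence sit less than a month apart and
`LOW_CONFIDENCE` when a step's log-likelihood margin falls below 3.

A CLI mirrors the library:

```bash
ehrcohort generate --task af_progression --n 100 --seed 7 --out corpus.jsonl
ehrcohort label-rules --in corpus.jsonl --out labels.jsonl --trace traces.jsonl
ehrcohort label-llm --in corpus.jsonl --out llm.jsonl --seed 7 --strategy onset
ehrcohort evaluate --pred labels.jsonl --gold corpus.jsonl --out report.json
```

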