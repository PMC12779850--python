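# Methods

## Task model

A patient is an ordered sequence of dated free-text discharge reports. A
`TaskSpec` defines an episodic-disease phenotype by three concepts and two
day windows anchored at the *debut* (the earliest report with an affirmed
mention of the debut concept outside the personal-history section):

| task | debut / progression concept | remission concept | remission window | progression window |
|---|---|---|---|---|
| `af_progression` | AF | sinus rhythm | [1, 30) days | [30, 730] days |
| `hf_decompensation` | HF | — | [1, 7) days | [7, 730] days |

Calendar arithmetic is fixed at 1 week = 7 days, 1 month = 30 days and
2 years = 730 days; the source phrasing ("between 1 month and 2 years")
does not define month/year arithmetic or boundary inclusivity, so the
progression window is closed (evidence dated exactly on day 30 or day 730
counts) and the remission window is half-open with its end pinned to the
progression start, making the four window classes a partition of the
integers. All window bounds live in `TaskSpec`, so alternative conventions
are configuration, not code changes.

Patient labels follow a fixed precedence: (a) no affirmed debut → −1;
(b) affirmed progression-concept evidence in a progression-window report →
1 — recurrence after a documented return to sinus rhythm is still
progression; (c) otherwise affirmed remission evidence at ≥ 1 day → 0 (for
HF, which has no remission concept, a debut with no later in-window episode
→ 0); (d) otherwise −1. Whether a later episode should override an earlier
remission finding is a genuine modelling choice; we resolve it in favour of
(b) because the clinical definition of progression is "recurrence or
permanence", not "no remission".

Same-date reports are ordered by report id — the data give no finer
timestamp, and a documented deterministic tie-break beats an undocumented
stable sort. Only report dates anchor time; intra-note temporal expressions
("hace dos años") are out of scope.

## Text stages

The section segmenter matches a configurable header lexicon
(case/diacritic-insensitively, line-anchored, colon-terminated); text before
the first header falls into `otros`, and section spans always partition the
text. Mention extraction runs a versioned Spanish surface-form lexicon
(YAML data files) over a length-preserving character fold of the text, so
spans index the original string; matches are word-boundary anchored (the
abbreviation "FA" never fires inside "grafa") and longest-first
non-overlapping. Negation is NegEx-style: a trigger phrase ("no", "sin",
"niega", "se descarta", "ausencia de", ...) within 5 tokens before the
mention, in the same sentence, with scope terminated by clause/contrast cues
(",", ";", "pero", "aunque"). The 5-token window follows the usual NegEx
convention and is configurable. These deterministic stages stand behind the
same contract (sections in, asserted mentions out) that statistical section
/ NER / negation models would fill; mentions in `antecedentes` are excluded
from debut and progression evidence, the conservative reading of what
section structure is for.

## Prompting strategies

All strategies are zero-shot and backend-agnostic (`complete(prompt) ->
str`, optional `score_labels`). Prompt bodies are authored, slot-compatible
ES/EN YAML data files; each carries a leading machine-readable
`[[step:...]]` tag that the deterministic test backends use to identify the
step — real model backends ignore it. Reports are embedded as delimited
blocks carrying their id and date.

Output parsing is strict by design: after diacritic folding, lowercasing and
trimming surrounding punctuation, the reply must equal exactly one allowed
label token; anything longer — even text containing the correct label — is a
`FORMAT_ERROR`. A step-level format error marks the whole patient
`FORMAT_ERROR` (value `None`), which every metric counts as wrong and
tallies separately: the quantity measures instruction following, not just
accuracy.

Aggregation of per-report step-2 decisions is not uniquely determined by the
class definitions; we mirror the rule pipeline's precedence: any progression
YES → 1; else sinus-rhythm evidence — a remission-step YES or a
progression-step NO (the 3-class step's NO *means* "ECG returning to sinus
rhythm") — → 0; else −1. The debut scan stops at its first YES; step 2 scans
all strictly-later reports and records every decision, which the stepwise
outcome taxonomy needs. A patient whose debut sits in the last report gets
−1 (nothing left to assess). For HF, step 2 is binary (Yes/No) and −1 is
reserved for no-debut patients.

The onset-guided date fragment comes in three renderings: numeric ISO dates,
written dates in the prompt language, or "Time since debut: N days".

## Synthetic cohorts

The generator is constructive: it first plans day offsets and decisive
events per report (debut at day 0; for gold 1 a progression mention at a
uniform in-window offset, optionally preceded by an early remission; for
gold 0 a remission mention, mostly within the first month; for gold −1
either no affirmed debut anywhere or a debut followed by nothing decisive),
then renders sectioned Spanish template notes whose planted sentences use
lexicon surface forms, and finally derives the gold label from the planted
affirmed events through the same `TaskSpec` window arithmetic the labeler
uses — one definition of the task, not two. Defaults emulate the study
conditions: 5.07 mean reports/patient for AF and 7.07 for HF (shifted
Poisson, minimum 1, minimum 2 when the target label needs post-debut
evidence), class mixes from the test partitions (AF 41/25/42 of 108; HF
32/25/43 of 100), inter-report gaps uniform in 20–240 days, report dates
starting 2015–2018.

Label-preserving perturbations: `negation_rate` inserts negated decoy
mentions of the disease concept; `distractor_rate` inserts affirmed
other-arrhythmia sentences; `contrary_ecg_rate` adds a sinus-rhythm ECG next
to the AF ECG — only in progression reports of gold-1 patients, the one
placement where the perturbation cannot change the label. The adversarial
cohorts push these to 1.0: pure-negation (gold 0/−1, every in-window disease
mention negated), other-arrhythmia (gold 0/−1, affirmed distractors
everywhere), and contrary-ECG (gold 1, both ECGs in one in-window report).

What the generator does *not* emulate: real lexical diversity, typos,
section-header variation beyond the lexicon, intra-note temporal language,
and realistic note length — long-history difficulty is represented by report
count, not note length. Perfect scores on clean synthetic cohorts therefore
validate the *contracts* (window arithmetic, negation scope, orchestration,
aggregation, parsing), not performance on real clinical text.

## Test backends

The oracle backend answers every prompt correctly by construction: it
resolves report blocks by id to the generator's planted-event bookkeeping,
parses the rendered date fragment (all three modes, both languages) to
recover the debut offset, and applies the class definitions. It is the
ground truth against which strategy orchestration is tested; wrapping it
with a fixed character budget (`TruncatingBackend`) reproduces the
long-context failure of concatenation while leaving per-report strategies
untouched, and `VerboseBackend` wraps correct answers in prose to exercise
the format-error policy. `score_labels` returns a fixed margin (default 4.0)
between the chosen label and the alternatives, so margin plumbing and
review-flag thresholds are testable end to end.

## Evaluation

Accuracy is exact-match over all patients with format errors counted wrong.
F1 is macro-averaged over the three classes — the unknown class is a
first-class outcome and the classes are imbalanced — with weighted F1
available; format-error predictions stay out of the 3×3 confusion matrix
but count as recall misses for their gold class. Cohen's κ uses the closed
form (p_o − p_e)/(1 − p_e) with the degenerate p_e = 1 case defined as 1
when observed agreement is also perfect. The stepwise taxonomy
(`CORRECT_WHOLE_HISTORY` / `CORRECT_FINAL_DECISION` / `INCORRECT`) compares
trace decisions to per-step gold derived from planted events; the
temporality audit counts YES decisions whose window does not license them;
margin summaries report per-group mean ± sd (sample sd) of patient-mean
margins and flag any patient with a step margin below 3, the default
manual-review threshold, alongside the sub-30-day debut-to-progression
`TEMPORALITY` flag.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; identical parameters
and seed give byte-identical corpora. The bundled checks use cohorts of
500–1,000 patients per task (10,000 samples for the window-partition check,
1,000 random vectors for the κ cross-check), sizes at which the binary
properties under test (exact equivalences, zero-count invariants) are
already fully exercised; everything runs in seconds on one CPU.

## Known limitations

* Lexicons and negation triggers are authored inventories, versioned but
  small; real deployments would extend them or swap in statistical models
  behind the same interfaces.
* No uncertainty/speculation class separate from negation.
* No UMLS/SNOMED normalisation, coreference, or intra-note temporal
  expression parsing.
* The bundled backends are test instruments; real-model adapters are the
  user's responsibility behind the backend contract, and real-text
  performance cannot be inferred from synthetic-cohort scores.
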