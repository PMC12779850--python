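"""Zero-shot orchestration strategies over a text-model backend.

Four ways to turn a multi-report history into one 3-class cohort label:

* concatenation — one call on the whole dated history (long-context probe);
* summarization — a worker call per report folds each note into a running
  summary; a manager call labels the final summary (n+1 calls);
* onset-guided — step 1 scans reports chronologically for the debut; step 2
  puts the debut date (numeric, written, or day-offset form) plus each later
  report into a 3-class prompt;
* chronology-guided — like onset-guided, but the orchestrator itself applies
  the task windows: remission prompts only for remission-window reports,
  progression prompts only for progression-window reports, and reports beyond
  the 2-year bound never reach the backend.

Aggregation to the patient label mirrors the rule pipeline's precedence:
any progression YES -> 1; else sinus-rhythm evidence (a remission YES or a
progression-step NO) -> 0; else -1. Tasks without a remission concept use a
binary step 2 (any YES -> 1, else 0; -1 is reserved for no-debut patients).
Any step-level format error marks the whole patient FORMAT_ERROR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .backends import ScoringBackend, TextBackend, format_report_block
from .prompts import (FORMAT_ERROR, NO, THREE_CLASS, TWO_CLASS, UNKNOWN, YES,
                      DISEASE_NAMES, LabelResponse, PromptTemplate,
                      label_set_phrase, load_templates, parse_label, render_date)
from .records import PatientHistory, build_timeline, days_between
from .tasks import TaskSpec
from .temporal import (DEBUT_SEARCH, PROGRESSION_CHECK, REMISSION_CHECK,
                       CohortLabel, Decision, StepRecord, WindowClass,
                       classify_window)

_DECISION = {YES: Decision.YES, NO: Decision.NO, UNKNOWN: Decision.UNKNOWN,
             FORMAT_ERROR: Decision.FORMAT_ERROR}


@dataclass
class PromptRecord:
    """One backend exchange, as written to the prompt log."""

    patient_id: str
    report_id: str
    step: str
    prompt: str
    raw: str
    parsed: Optional[str]  # None for worker (summary) calls
    scores: Optional[dict] = None
    margin: Optional[float] = None


@dataclass
class StrategyRun:
    """Outcome of one strategy on one patient."""

    label: CohortLabel
    prompt_log: list[PromptRecord] = field(default_factory=list)
    summaries: list[str] = field(default_factory=list)

    @property
    def n_calls(self) -> int:
        return len(self.prompt_log)


def _disease(spec: TaskSpec, language: str) -> str:
    return DISEASE_NAMES.get((spec.name, language), spec.name)


def _decisive_call(backend: TextBackend, prompt: str, allowed: Sequence[str],
                   language: str) -> LabelResponse:
    raw = backend.complete(prompt)
    response = parse_label(raw, allowed=allowed, language=language)
    if isinstance(backend, ScoringBackend):
        try:
            scores = dict(backend.score_labels(prompt, list(allowed)))
        except Exception:
            scores = None
        if scores:
            ordered = sorted(scores.values(), reverse=True)
            response.scores = scores
            response.margin = ordered[0] - ordered[1] if len(ordered) > 1 else None
    return response


def _step2_allowed(spec: TaskSpec) -> tuple[str, ...]:
    return THREE_CLASS if spec.remission_concept is not None else TWO_CLASS


def _finalize(value: Optional[int], trace: list[StepRecord],
              log: list[PromptRecord], summaries: Optional[list[str]] = None) -> StrategyRun:
    had_format_error = any(s.decision is Decision.FORMAT_ERROR for s in trace)
    if had_format_error:
        label = CohortLabel(value=None, trace=trace, format_error=True)
    else:
        label = CohortLabel(value=value, trace=trace)
    return StrategyRun(label=label, prompt_log=log, summaries=summaries or [])


# ---------------------------------------------------------------------------


def run_concatenation(history: PatientHistory, backend: TextBackend,
                      templates: Optional[dict[str, PromptTemplate]] = None,
                      spec: Optional[TaskSpec] = None,
                      language: str = "es") -> StrategyRun:
    """One backend call on the full concatenated, date-prefixed history."""
    from .tasks import af_progression
    spec = spec if spec is not None else af_progression()
    templates = templates if templates is not None else load_templates(language)
    history = build_timeline(history)
    if not history.reports:
        return StrategyRun(label=CohortLabel(value=-1))
    allowed = THREE_CLASS
    prompt = templates["concatenation"].render(
        report_blocks="\n".join(format_report_block(r) for r in history.reports),
        disease=_disease(spec, language),
        label_set=label_set_phrase(allowed, language),
    )
    response = _decisive_call(backend, prompt, allowed, language)
    decision = _DECISION[response.parsed]
    trace = [StepRecord("*", "concatenation", decision, margin=response.margin)]
    log = [PromptRecord(history.patient_id, "*", "concatenation", prompt,
                        response.raw, response.parsed, response.scores, response.margin)]
    value = {YES: 1, NO: 0, UNKNOWN: -1}.get(response.parsed)
    return _finalize(value, trace, log)


def run_summarization(history: PatientHistory, backend: TextBackend,
                      templates: Optional[dict[str, PromptTemplate]] = None,
                      spec: Optional[TaskSpec] = None,
                      language: str = "es") -> StrategyRun:
    """Worker-per-report running summary, then one manager decision.

    Exactly n+1 backend calls for an n-report history; all intermediate
    summaries are retained.
    """
    from .tasks import af_progression
    spec = spec if spec is not None else af_progression()
    templates = templates if templates is not None else load_templates(language)
    history = build_timeline(history)
    if not history.reports:
        return StrategyRun(label=CohortLabel(value=-1))
    disease = _disease(spec, language)
    summaries: list[str] = []
    summary = ""
    log: list[PromptRecord] = []
    for report in history.reports:
        prompt = templates["summarization_worker"].render(
            summary=summary, report_block=format_report_block(report), disease=disease)
        summary = backend.complete(prompt)
        summaries.append(summary)
        log.append(PromptRecord(history.patient_id, report.report_id,
                                "summarization_worker", prompt, summary, None))
    allowed = THREE_CLASS
    prompt = templates["summarization_manager"].render(
        summary=summary, disease=disease, label_set=label_set_phrase(allowed, language))
    response = _decisive_call(backend, prompt, allowed, language)
    trace = [StepRecord("*", "summarization_manager", _DECISION[response.parsed],
                        margin=response.margin)]
    log.append(PromptRecord(history.patient_id, "*", "summarization_manager", prompt,
                            response.raw, response.parsed, response.scores, response.margin))
    value = {YES: 1, NO: 0, UNKNOWN: -1}.get(response.parsed)
    return _finalize(value, trace, log, summaries)


def _debut_scan(history: PatientHistory, backend: TextBackend,
                templates: dict[str, PromptTemplate], disease: str, language: str,
                trace: list[StepRecord], log: list[PromptRecord]):
    """Step 1: chronological binary debut search; stops at the first YES."""
    for idx, report in enumerate(history.reports):
        prompt = templates["onset_debut"].render(
            report_block=format_report_block(report), disease=disease)
        response = _decisive_call(backend, prompt, TWO_CLASS, language)
        trace.append(StepRecord(report.report_id, DEBUT_SEARCH,
                                _DECISION[response.parsed], margin=response.margin))
        log.append(PromptRecord(history.patient_id, report.report_id, DEBUT_SEARCH,
                                prompt, response.raw, response.parsed,
                                response.scores, response.margin))
        if response.parsed == YES:
            return idx, report.date
    return None, None


def run_onset_guided(history: PatientHistory, backend: TextBackend,
                     templates: Optional[dict[str, PromptTemplate]] = None,
                     spec: Optional[TaskSpec] = None, date_mode: str = "num",
                     language: str = "es") -> StrategyRun:
    """Two-step decomposition: find the debut, then label each later report
    with the debut date rendered in ``date_mode`` (num / nl / dur)."""
    from .tasks import af_progression
    spec = spec if spec is not None else af_progression()
    templates = templates if templates is not None else load_templates(language)
    history = build_timeline(history)
    disease = _disease(spec, language)
    trace: list[StepRecord] = []
    log: list[PromptRecord] = []
    debut_idx, debut_date = _debut_scan(history, backend, templates, disease, language,
                                        trace, log)
    if debut_idx is None:
        return _finalize(-1, trace, log)
    allowed = _step2_allowed(spec)
    any_yes = any_no = False
    for report in history.reports[debut_idx + 1:]:
        fragment = render_date(debut_date, report.date, date_mode, language)
        prompt = templates["onset_progression"].render(
            date_fragment=fragment, report_block=format_report_block(report),
            disease=disease, label_set=label_set_phrase(allowed, language))
        response = _decisive_call(backend, prompt, allowed, language)
        window = classify_window(debut_date, report.date, spec)
        trace.append(StepRecord(report.report_id, PROGRESSION_CHECK,
                                _DECISION[response.parsed], window,
                                days_between(debut_date, report.date), response.margin))
        log.append(PromptRecord(history.patient_id, report.report_id, PROGRESSION_CHECK,
                                prompt, response.raw, response.parsed,
                                response.scores, response.margin))
        any_yes = any_yes or response.parsed == YES
        any_no = any_no or response.parsed == NO
    if any_yes:
        value = 1
    elif spec.remission_concept is None:
        value = 0
    elif any_no:
        value = 0
    else:
        value = -1
    return _finalize(value, trace, log)


def run_chronology_guided(history: PatientHistory, backend: TextBackend,
                          templates: Optional[dict[str, PromptTemplate]] = None,
                          spec: Optional[TaskSpec] = None, date_mode: str = "num",
                          language: str = "es") -> StrategyRun:
    """Three-step decomposition with orchestrator-enforced windows.

    Remission prompts go only to remission-window reports, progression
    prompts only to progression-window reports; pre-debut and beyond-2-years
    reports are recorded as SKIPPED and never reach the backend.
    """
    from .tasks import af_progression
    spec = spec if spec is not None else af_progression()
    templates = templates if templates is not None else load_templates(language)
    history = build_timeline(history)
    disease = _disease(spec, language)
    trace: list[StepRecord] = []
    log: list[PromptRecord] = []
    debut_idx, debut_date = _debut_scan(history, backend, templates, disease, language,
                                        trace, log)
    if debut_idx is None:
        return _finalize(-1, trace, log)
    allowed = _step2_allowed(spec)
    prog_yes = sinus_evidence = False
    for report in history.reports[debut_idx + 1:]:
        window = classify_window(debut_date, report.date, spec)
        offset = days_between(debut_date, report.date)
        fragment = render_date(debut_date, report.date, date_mode, language)
        if window is WindowClass.REMISSION_WINDOW and spec.remission_concept is not None:
            prompt = templates["chronology_remission"].render(
                date_fragment=fragment, report_block=format_report_block(report),
                disease=disease)
            response = _decisive_call(backend, prompt, TWO_CLASS, language)
            trace.append(StepRecord(report.report_id, REMISSION_CHECK,
                                    _DECISION[response.parsed], window, offset,
                                    response.margin))
            log.append(PromptRecord(history.patient_id, report.report_id, REMISSION_CHECK,
                                    prompt, response.raw, response.parsed,
                                    response.scores, response.margin))
            sinus_evidence = sinus_evidence or response.parsed == YES
        elif window is WindowClass.PROGRESSION_WINDOW:
            prompt = templates["chronology_progression"].render(
                date_fragment=fragment, report_block=format_report_block(report),
                disease=disease, label_set=label_set_phrase(allowed, language))
            response = _decisive_call(backend, prompt, allowed, language)
            trace.append(StepRecord(report.report_id, PROGRESSION_CHECK,
                                    _DECISION[response.parsed], window, offset,
                                    response.margin))
            log.append(PromptRecord(history.patient_id, report.report_id,
                                    PROGRESSION_CHECK, prompt, response.raw,
                                    response.parsed, response.scores, response.margin))
            prog_yes = prog_yes or response.parsed == YES
            if spec.remission_concept is not None:
                sinus_evidence = sinus_evidence or response.parsed == NO
        else:
            step = REMISSION_CHECK if window is WindowClass.REMISSION_WINDOW \
                else PROGRESSION_CHECK
            trace.append(StepRecord(report.report_id, step, Decision.SKIPPED,
                                    window, offset))
    if prog_yes:
        value = 1
    elif spec.remission_concept is None:
        value = 0
    elif sinus_evidence:
        value = 0
    else:
        value = -1
    return _finalize(value, trace, log)


STRATEGIES = {
    "concat": run_concatenation,
    "summarize": run_summarization,
    "onset": run_onset_guided,
    "chronology": run_chronology_guided,
}
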