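"""Text-model backend contract and the deterministic test backends.

A backend is anything with ``complete(prompt) -> str`` (optionally
``score_labels(prompt, labels) -> {label: log_likelihood}``). Real
instruction-tuned models plug in behind the same contract; the package's own
test surface uses:

* :class:`OracleBackend` — answers every prompt correctly by reading the
  synthetic generator's planted-event bookkeeping (it locates report blocks
  by their ids and applies the task's window arithmetic to the planted
  affirmed events). It is the ground-truth backend for strategy contracts.
* :class:`TruncatingBackend` — imposes a fixed context budget, emulating the
  long-context failure of concatenated histories.
* :class:`VerboseBackend` — wraps answers in prose, violating the
  label-only instruction (format-error policy probe).
* :class:`ScriptedBackend` — replays a fixed script.
"""

from __future__ import annotations

import datetime
import re
from typing import Callable, Mapping, Optional, Protocol, Sequence, runtime_checkable

from .prompts import FORMAT_ERROR, NO, THREE_CLASS, UNKNOWN, YES, parse_label
from .records import DischargeReport, days_between
from .synth import PlantedEvent, SyntheticPatient, gold_from_planted
from .tasks import TaskSpec


@runtime_checkable
class TextBackend(Protocol):
    def complete(self, prompt: str) -> str: ...


@runtime_checkable
class ScoringBackend(TextBackend, Protocol):
    def score_labels(self, prompt: str, labels: Sequence[str]) -> Mapping[str, float]: ...


class BackendError(RuntimeError):
    """A backend could not produce a reply for a prompt."""


# ---------------------------------------------------------------------------
# report blocks: how strategies embed reports in prompts

def format_report_block(report: DischargeReport) -> str:
    """Delimited report block carrying the id and date, as used in prompts."""
    return (f"[[informe id={report.report_id} fecha={report.date.isoformat()}]]\n"
            f"{report.text.rstrip()}\n[[fin informe]]")


_BLOCK_RE = re.compile(
    r"\[\[informe id=(\S+) fecha=(\d{4}-\d{2}-\d{2})\]\]\n(.*?)\n\[\[fin informe\]\]",
    re.DOTALL,
)
_STEP_RE = re.compile(r"\[\[step:(\w+)\]\]")

_SUMMARY_RE = re.compile(r"<<RESUMEN>>\n(.*?)<<FIN RESUMEN>>", re.DOTALL)
_EVENT_LINE_RE = re.compile(r"^EVENTO (\S+) (\d{4}-\d{2}-\d{2})$", re.MULTILINE)

# date fragments (both languages)
_DUR_RE = re.compile(r"(?:Time since debut|Tiempo desde el debut):\s*(-?\d+)\s*(?:days|d[ií]as)")
_NUM_DEBUT_RE = re.compile(r"(?:Debut date|Fecha del debut):\s*(\d{4}-\d{2}-\d{2})")
_NUM_REPORT_RE = re.compile(
    r"(?:Current report date|Fecha del informe actual):\s*(\d{4}-\d{2}-\d{2})")
_NL_ES_RE = r"(\d{1,2}) de (\w+) de (\d{4})"
_NL_EN_RE = r"(\w+) (\d{1,2}), (\d{4})"
_NL_DEBUT_ES = re.compile(r"Fecha del debut:\s*" + _NL_ES_RE)
_NL_REPORT_ES = re.compile(r"Fecha del informe actual:\s*" + _NL_ES_RE)
_NL_DEBUT_EN = re.compile(r"Debut date:\s*" + _NL_EN_RE)
_NL_REPORT_EN = re.compile(r"Current report date:\s*" + _NL_EN_RE)

_MONTH_INDEX = {}
for i, name in enumerate(("enero", "febrero", "marzo", "abril", "mayo", "junio", "julio",
                          "agosto", "septiembre", "octubre", "noviembre", "diciembre"), 1):
    _MONTH_INDEX[name] = i
for i, name in enumerate(("january", "february", "march", "april", "may", "june", "july",
                          "august", "september", "october", "november", "december"), 1):
    _MONTH_INDEX[name] = i


def _parse_nl_date(match: re.Match, spanish: bool) -> Optional[datetime.date]:
    try:
        if spanish:
            day, month, year = match.group(1), match.group(2), match.group(3)
        else:
            month, day, year = match.group(1), match.group(2), match.group(3)
        return datetime.date(int(year), _MONTH_INDEX[month.lower()], int(day))
    except (KeyError, ValueError):
        return None


def parse_offset_days(prompt: str) -> Optional[int]:
    """Recover the debut-to-report offset from a rendered date fragment."""
    m = _DUR_RE.search(prompt)
    if m:
        return int(m.group(1))
    md, mr = _NUM_DEBUT_RE.search(prompt), _NUM_REPORT_RE.search(prompt)
    if md and mr:
        return days_between(datetime.date.fromisoformat(md.group(1)),
                            datetime.date.fromisoformat(mr.group(1)))
    for debut_re, report_re, spanish in ((_NL_DEBUT_ES, _NL_REPORT_ES, True),
                                         (_NL_DEBUT_EN, _NL_REPORT_EN, False)):
        md, mr = debut_re.search(prompt), report_re.search(prompt)
        if md and mr:
            d, r = _parse_nl_date(md, spanish), _parse_nl_date(mr, spanish)
            if d and r:
                return days_between(d, r)
    return None


# ---------------------------------------------------------------------------

_WORD = {YES: "Yes", NO: "No", UNKNOWN: "Unknown"}


class OracleBackend:
    """Answers prompts from the generator's planted-event bookkeeping.

    ``margin`` is the fixed log-likelihood gap reported by ``score_labels``
    between the chosen label and the alternatives.
    """

    def __init__(self, cohort: Sequence[SyntheticPatient], spec: TaskSpec,
                 margin: float = 4.0):
        self.spec = spec
        self.margin = margin
        self._events: dict[str, list[PlantedEvent]] = {}
        for patient in cohort:
            for e in patient.planted_events:
                self._events.setdefault(e.report_id, []).append(e)

    # -- helpers ------------------------------------------------------------

    def _affirmed(self, report_id: str, concept: str) -> bool:
        return any(not e.negated and e.section != "antecedentes" and e.concept == concept
                   for e in self._events.get(report_id, ()))

    def _blocks(self, prompt: str) -> list[tuple[str, datetime.date]]:
        return [(m.group(1), datetime.date.fromisoformat(m.group(2)))
                for m in _BLOCK_RE.finditer(prompt)]

    # -- contract -----------------------------------------------------------

    def complete(self, prompt: str) -> str:
        m = _STEP_RE.search(prompt)
        if not m:
            raise BackendError("prompt carries no [[step:...]] marker")
        step = m.group(1)
        handler = getattr(self, f"_step_{step}", None)
        if handler is None:
            raise BackendError(f"unknown step {step!r}")
        return handler(prompt)

    def score_labels(self, prompt: str, labels: Sequence[str]) -> dict[str, float]:
        reply = parse_label(self.complete(prompt), allowed=labels)
        top = reply.parsed if reply.parsed != FORMAT_ERROR else labels[0]
        return {lab: -1.0 if lab == top else -1.0 - self.margin for lab in labels}

    # -- steps --------------------------------------------------------------

    def _step_onset_debut(self, prompt: str) -> str:
        blocks = self._blocks(prompt)
        if not blocks:
            raise BackendError("onset_debut prompt lacks a report block")
        rid, _ = blocks[0]
        return _WORD[YES] if self._affirmed(rid, self.spec.debut_concept) else _WORD[NO]

    def _progression_answer(self, rid: str, offset: Optional[int]) -> str:
        r0, _ = self.spec.remission_window_days
        p0, p1 = self.spec.progression_window_days
        if offset is not None and p0 <= offset <= p1 and \
                self._affirmed(rid, self.spec.progression_concept):
            return _WORD[YES]
        if self.spec.remission_concept is None:
            return _WORD[NO]
        if offset is not None and r0 <= offset <= p1 and \
                self._affirmed(rid, self.spec.remission_concept):
            return _WORD[NO]
        return _WORD[UNKNOWN]

    def _step_onset_progression(self, prompt: str) -> str:
        blocks = self._blocks(prompt)
        if not blocks:
            raise BackendError("onset_progression prompt lacks a report block")
        rid, _ = blocks[0]
        return self._progression_answer(rid, parse_offset_days(prompt))

    def _step_chronology_remission(self, prompt: str) -> str:
        blocks = self._blocks(prompt)
        if not blocks:
            raise BackendError("chronology_remission prompt lacks a report block")
        rid, _ = blocks[0]
        if self.spec.remission_concept is None:
            return _WORD[NO]
        return _WORD[YES] if self._affirmed(rid, self.spec.remission_concept) else _WORD[NO]

    def _step_chronology_progression(self, prompt: str) -> str:
        blocks = self._blocks(prompt)
        if not blocks:
            raise BackendError("chronology_progression prompt lacks a report block")
        rid, _ = blocks[0]
        if self._affirmed(rid, self.spec.progression_concept):
            return _WORD[YES]
        if self.spec.remission_concept is not None and \
                self._affirmed(rid, self.spec.remission_concept):
            return _WORD[NO]
        return _WORD[UNKNOWN] if self.spec.remission_concept is not None else _WORD[NO]

    def _collect_events(self, blocks: Sequence[tuple[str, datetime.date]]) -> list[PlantedEvent]:
        events: list[PlantedEvent] = []
        for rid, _ in blocks:
            events.extend(self._events.get(rid, ()))
        return events

    def _label_word(self, value: int) -> str:
        return {1: _WORD[YES], 0: _WORD[NO], -1: _WORD[UNKNOWN]}[value]

    def _step_concatenation(self, prompt: str) -> str:
        events = self._collect_events(self._blocks(prompt))
        return self._label_word(gold_from_planted(events, self.spec))

    def _step_summarization_worker(self, prompt: str) -> str:
        m = _SUMMARY_RE.search(prompt)
        previous = m.group(1).strip() if m else ""
        lines = [ln for ln in previous.splitlines() if ln.strip()]
        for rid, date in self._blocks(prompt):
            for e in self._events.get(rid, ()):
                if not e.negated and e.section != "antecedentes":
                    lines.append(f"EVENTO {e.concept} {e.date.isoformat()}")
        return "\n".join(lines) if lines else "Sin hallazgos relevantes."

    def _step_summarization_manager(self, prompt: str) -> str:
        m = _SUMMARY_RE.search(prompt)
        summary = m.group(1) if m else ""
        events = [
            PlantedEvent(concept=em.group(1),
                         date=datetime.date.fromisoformat(em.group(2)),
                         negated=False, report_id="summary", section="evolucion")
            for em in _EVENT_LINE_RE.finditer(summary)
        ]
        return self._label_word(gold_from_planted(events, self.spec))


class TruncatingBackend:
    """Context-budget wrapper: the inner backend sees only the first
    ``max_chars`` characters of every prompt."""

    def __init__(self, inner: TextBackend, max_chars: int):
        self.inner = inner
        self.max_chars = max_chars

    def complete(self, prompt: str) -> str:
        return self.inner.complete(prompt[: self.max_chars])

    def score_labels(self, prompt: str, labels: Sequence[str]) -> Mapping[str, float]:
        if not isinstance(self.inner, ScoringBackend):
            raise BackendError("inner backend does not score labels")
        return self.inner.score_labels(prompt[: self.max_chars], labels)


class VerboseBackend:
    """Instruction-violating wrapper: embeds the (correct) answer in prose."""

    def __init__(self, inner: TextBackend, language: str = "es"):
        self.inner = inner
        self.language = language

    def complete(self, prompt: str) -> str:
        answer = self.inner.complete(prompt)
        if self.language == "es":
            return f"Tras revisar la historia clínica, la respuesta es {answer}."
        return f"After reviewing the clinical history, the answer is {answer}."


class ScriptedBackend:
    """Replays a fixed reply function or sequence (for tests)."""

    def __init__(self, script: Callable[[str], str] | Sequence[str],
                 scores: Optional[Callable[[str, Sequence[str]], Mapping[str, float]]] = None):
        self._script = script
        self._i = 0
        self._scores = scores

    def complete(self, prompt: str) -> str:
        if callable(self._script):
            return self._script(prompt)
        if self._i >= len(self._script):
            raise BackendError("script exhausted")
        reply = self._script[self._i]
        self._i += 1
        return reply

    def score_labels(self, prompt: str, labels: Sequence[str]) -> Mapping[str, float]:
        if self._scores is None:
            raise BackendError("no scores scripted")
        return self._scores(prompt, labels)
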