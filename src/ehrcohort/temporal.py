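"""Temporal decision logic: window classification of each report against the
debut date, and aggregation of per-report evidence into the 3-class patient
label (1 progression / 0 non-progression / -1 unknown).

Decision rules, in precedence order (AF defaults):

a. no affirmed debut mention anywhere -> -1;
b. any affirmed progression-concept mention in a progression-window report
   -> 1 (recurrence after a return to sinus rhythm is still progression);
c. else any affirmed remission-concept mention at offset >= 1 day (remission
   or progression window) -> 0; for tasks without a remission concept (HF),
   a debut with no in-window progression evidence -> 0;
d. else -> -1.

Mentions found in the "antecedentes" (personal history) section are excluded
from debut and progression evidence by default: section structure is what
separates past history from the current episode.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import nlp
from .records import PatientHistory, build_timeline, days_between
from .tasks import TaskSpec

DEFAULT_EXCLUDED_SECTIONS = frozenset({"antecedentes"})


class WindowClass(enum.Enum):
    PRE_DEBUT = "PRE_DEBUT"
    REMISSION_WINDOW = "REMISSION_WINDOW"
    PROGRESSION_WINDOW = "PROGRESSION_WINDOW"
    POST_WINDOW = "POST_WINDOW"


class Decision(str, enum.Enum):
    YES = "YES"
    NO = "NO"
    UNKNOWN = "UNKNOWN"
    FORMAT_ERROR = "FORMAT_ERROR"
    SKIPPED = "SKIPPED"


# step names shared by the rule pipeline and the prompting strategies
DEBUT_SEARCH = "debut_search"
REMISSION_CHECK = "remission_check"
PROGRESSION_CHECK = "progression_check"


@dataclass(frozen=True)
class StepRecord:
    """One per-report decision in a labeling trace."""

    report_id: str
    step: str
    decision: Decision
    window: Optional[WindowClass] = None
    offset_days: Optional[int] = None
    margin: Optional[float] = None


@dataclass
class CohortLabel:
    """Patient-level outcome with its decision trace.

    ``value`` is 1/0/-1, or ``None`` when the run ended in a format error
    (instruction-violating backend output); such patients count as wrong in
    every metric and are tallied separately.
    """

    value: Optional[int]
    trace: list[StepRecord] = field(default_factory=list)
    format_error: bool = False

    def __post_init__(self) -> None:
        if self.value not in (1, 0, -1, None):
            raise ValueError(f"label value must be 1/0/-1/None, got {self.value!r}")
        if self.value is None and not self.format_error:
            raise ValueError("value None requires format_error=True")


def classify_window(debut: datetime.date, report: datetime.date, spec: TaskSpec) -> WindowClass:
    """Which evaluation window a report falls in relative to the debut.

    AF defaults (remission [1, 30), progression [30, 730]): offset d < 1 ->
    PRE_DEBUT; 1 <= d < 30 -> REMISSION_WINDOW; 30 <= d <= 730 ->
    PROGRESSION_WINDOW; d > 730 -> POST_WINDOW. The four classes partition
    the integers.
    """
    d = days_between(debut, report)
    r0, _ = spec.remission_window_days
    p0, p1 = spec.progression_window_days
    if d < r0:
        return WindowClass.PRE_DEBUT
    if d < p0:
        return WindowClass.REMISSION_WINDOW
    if d <= p1:
        return WindowClass.PROGRESSION_WINDOW
    return WindowClass.POST_WINDOW


def affirmed(mentions: Sequence[nlp.ClinicalMention], concept: str,
             excluded_sections: frozenset[str] = DEFAULT_EXCLUDED_SECTIONS) -> bool:
    """Is there an affirmed mention of *concept* outside excluded sections?"""
    return any(
        m.concept == concept and not m.negated and m.section not in excluded_sections
        for m in mentions
    )


def find_debut(
    history: PatientHistory,
    spec: TaskSpec,
    mentions_per_report: Mapping[str, Sequence[nlp.ClinicalMention]],
    excluded_sections: frozenset[str] = DEFAULT_EXCLUDED_SECTIONS,
) -> Optional[tuple[str, datetime.date]]:
    """Earliest report with an affirmed debut-concept mention, or None."""
    for report in history.reports:
        if affirmed(mentions_per_report.get(report.report_id, ()), spec.debut_concept,
                    excluded_sections):
            return report.report_id, report.date
    return None


def label_patient_rule_based(
    history: PatientHistory,
    spec: TaskSpec,
    lexicon: dict | None = None,
    excluded_sections: frozenset[str] = DEFAULT_EXCLUDED_SECTIONS,
) -> CohortLabel:
    """Run the full rule pipeline on one patient.

    Rebuilds the timeline, extracts mentions per report, finds the debut and
    applies rules (a)-(d); every per-report step lands in the trace.
    """
    history = build_timeline(history)
    mentions = {r.report_id: nlp.extract_mentions(r, lexicon=lexicon) for r in history.reports}
    trace: list[StepRecord] = []

    debut = None
    for report in history.reports:
        hit = affirmed(mentions[report.report_id], spec.debut_concept, excluded_sections)
        trace.append(StepRecord(report.report_id, DEBUT_SEARCH,
                                Decision.YES if hit else Decision.NO))
        if hit:
            debut = (report.report_id, report.date)
            break
    if debut is None:
        return CohortLabel(value=-1, trace=trace)
    debut_id, debut_date = debut

    progression_fired = False
    remission_fired = False
    seen_debut = False
    for report in history.reports:
        if report.report_id == debut_id:
            seen_debut = True
            continue
        if not seen_debut:
            continue
        window = classify_window(debut_date, report.date, spec)
        offset = days_between(debut_date, report.date)
        ms = mentions[report.report_id]

        prog = window is WindowClass.PROGRESSION_WINDOW and affirmed(
            ms, spec.progression_concept, excluded_sections)
        trace.append(StepRecord(report.report_id, PROGRESSION_CHECK,
                                Decision.YES if prog else Decision.NO, window, offset))
        progression_fired = progression_fired or prog

        if spec.remission_concept is not None:
            in_rem = window in (WindowClass.REMISSION_WINDOW, WindowClass.PROGRESSION_WINDOW)
            rem = in_rem and affirmed(ms, spec.remission_concept, excluded_sections)
            trace.append(StepRecord(report.report_id, REMISSION_CHECK,
                                    Decision.YES if rem else Decision.NO, window, offset))
            remission_fired = remission_fired or rem

    if progression_fired:
        value = 1
    elif spec.remission_concept is None:
        value = 0  # debut documented, no later in-window episode
    elif remission_fired:
        value = 0
    else:
        value = -1
    return CohortLabel(value=value, trace=trace)


TEMPORALITY = "TEMPORALITY"
LOW_CONFIDENCE = "LOW_CONFIDENCE"


def review_flags(
    label: CohortLabel,
    margins: Optional[Sequence[float]] = None,
    gap_threshold_days: int = 30,
    margin_threshold: float = 3.0,
) -> list[str]:
    """Manual-review flags for one labeled patient.

    TEMPORALITY: the debut and the report that fired the progression rule lie
    less than ``gap_threshold_days`` apart (high-confidence temporality
    mistakes cluster there). LOW_CONFIDENCE: some step's log-likelihood
    margin falls below ``margin_threshold``.
    """
    flags: list[str] = []
    for step in label.trace:
        if (step.step == PROGRESSION_CHECK and step.decision is Decision.YES
                and step.offset_days is not None and step.offset_days < gap_threshold_days):
            flags.append(TEMPORALITY)
            break
    step_margins = [s.margin for s in label.trace if s.margin is not None]
    if margins is not None:
        step_margins.extend(margins)
    if any(m < margin_threshold for m in step_margins):
        flags.append(LOW_CONFIDENCE)
    return flags
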