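"""Synthetic Spanish discharge-report cohorts with known ground truth.

Patients are built constructively: decisive clinical events (debut episode,
recurrence, return to sinus rhythm) are *planted* into template notes at
controlled day offsets, and the gold label is derived from the planted
affirmed events through the same window arithmetic the labeler uses (single
source of truth in :class:`~ehrcohort.tasks.TaskSpec`). Adversarial cohorts
reproduce the three probe families that mislead text models: negated disease
mentions, distractor arrhythmias, and two contrary ECGs in one report.

Default rates emulate the study datasets: 5.07 reports/patient for AF
progression, 7.07 for HF decompensation, and class mixes matching the test
partitions (AF 41/25/42 of 108; HF 32/25/43 of 100). Notes are short
template notes; long-history difficulty is emulated by report count, not by
note length.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import DischargeReport, PatientHistory, build_timeline, days_between
from .tasks import (AF, HF, OTHER_ARRHYTHMIA, SINUS_RHYTHM, TaskSpec,
                    af_progression, hf_decompensation)

_MAX_SEED = 2**31 - 1


class GenerationError(ValueError):
    """Raised when the requested patient cannot be constructed."""


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    ``class_mix`` gives probabilities for labels (1, 0, -1) in that order.
    ``negation_rate`` is the per-report probability of inserting a *negated*
    decoy mention of the disease concept; ``distractor_rate`` the per-report
    probability of an affirmed other-arrhythmia sentence; neither changes the
    gold label. ``contrary_ecg_rate`` applies only to progression reports of
    gold-1 patients (adding a sinus-rhythm ECG next to the AF ECG), the one
    place the perturbation is label-preserving.
    """

    n_patients: int = 108
    class_mix: tuple[float, float, float] = (41 / 108, 25 / 108, 42 / 108)
    mean_reports_per_patient: float = 5.07
    report_gap_days: tuple[int, int] = (20, 240)
    negation_rate: float = 0.1
    distractor_rate: float = 0.0
    contrary_ecg_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for r in (self.negation_rate, self.distractor_rate, self.contrary_ecg_rate, *self.class_mix):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mean_reports_per_patient < 1:
            raise ValueError("mean_reports_per_patient must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


def default_params(spec: TaskSpec, **overrides) -> GeneratorParams:
    """Study-condition defaults for a built-in task."""
    if spec.name == "hf_decompensation":
        base = dict(n_patients=100, class_mix=(32 / 100, 25 / 100, 43 / 100),
                    mean_reports_per_patient=7.07)
    else:
        base = dict(n_patients=108, class_mix=(41 / 108, 25 / 108, 42 / 108),
                    mean_reports_per_patient=5.07)
    base.update(overrides)
    return GeneratorParams(**base)


@dataclass(frozen=True)
class PlantedEvent:
    """Bookkeeping record of one concept mention written into a note."""

    concept: str
    date: datetime.date
    negated: bool
    report_id: str
    section: str


@dataclass
class SyntheticPatient:
    history: PatientHistory
    gold_label: int
    planted_events: list[PlantedEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gold arithmetic from planted events (the generator-side oracle)

_EXCLUDED = frozenset({"antecedentes"})


def gold_from_planted(events: Sequence[PlantedEvent], spec: TaskSpec) -> int:
    """Patient label implied by the planted affirmed events under the task windows."""
    affirmed = [e for e in events if not e.negated and e.section not in _EXCLUDED]
    debut_dates = [e.date for e in affirmed if e.concept == spec.debut_concept]
    if not debut_dates:
        return -1
    debut = min(debut_dates)
    r0, _ = spec.remission_window_days
    p0, p1 = spec.progression_window_days
    prog = any(
        e.concept == spec.progression_concept and p0 <= days_between(debut, e.date) <= p1
        for e in affirmed
    )
    if prog:
        return 1
    if spec.remission_concept is None:
        return 0
    rem = any(
        e.concept == spec.remission_concept and r0 <= days_between(debut, e.date) <= p1
        for e in affirmed
    )
    return 0 if rem else -1


# ---------------------------------------------------------------------------
# note templating

_SURFACES = {
    AF: ("fibrilación auricular", "FA", "ACxFA", "fibrilación auricular paroxística"),
    SINUS_RHYTHM: ("ritmo sinusal", "RS"),
    HF: ("insuficiencia cardíaca", "IC", "insuficiencia cardíaca congestiva"),
    OTHER_ARRHYTHMIA: ("flutter auricular", "taquicardia ventricular",
                       "taquicardia supraventricular", "extrasístoles ventriculares"),
}

_FILLER = {
    "antecedentes": ("HTA en tratamiento farmacológico.", "Dislipemia.",
                     "Diabetes mellitus tipo 2.", "Exfumador desde hace 5 años.",
                     "Sin alergias medicamentosas conocidas."),
    "enfermedad_actual": ("Paciente que acude por disnea de esfuerzo.",
                          "Acude a urgencias por palpitaciones.",
                          "Ingreso programado para estudio.",
                          "Refiere malestar general de varios días."),
    "evolucion": ("Buena evolución clínica durante el ingreso.",
                  "Paciente estable hemodinámicamente.",
                  "Afebril durante toda la estancia."),
    "ecg": ("Trazado basal con buena calidad de registro.",),
    "juicio_diagnostico": ("Dolor torácico atípico.", "Bronquitis aguda.",
                           "Síncope vasovagal."),
}

# sentence templates by (role, in_ecg_section); {x} is the surface form
_AFFIRMED_DEBUT = ("Primer episodio documentado de {x}.", "{x} de nueva aparición.",
                   "Debut de {x} durante el ingreso.")
_AFFIRMED_PROG = ("Nuevo episodio de {x}.", "Recurrencia de {x}.",
                  "{x} persistente a pesar del tratamiento.")
_AFFIRMED_PROG_ECG = ("{x} con respuesta ventricular rápida.",)
_AFFIRMED_REM_ECG = ("{x} a 70 lpm.", "{x} sin alteraciones de la repolarización.")
_NEGATED = ("No se observa {x}.", "Se descarta {x}.", "Sin datos de {x}.")
_DISTRACTOR = ("Se objetiva {x}.", "Episodio autolimitado de {x}.")

_SECTION_ORDER = ("antecedentes", "enfermedad_actual", "evolucion", "ecg", "juicio_diagnostico")
_HEADERS = {
    "antecedentes": "ANTECEDENTES",
    "enfermedad_actual": "ENFERMEDAD ACTUAL",
    "evolucion": "EVOLUCIÓN",
    "ecg": "ECG",
    "juicio_diagnostico": "JUICIO DIAGNÓSTICO",
}


def _pick(rng: np.random.Generator, seq: Sequence[str]) -> str:
    return seq[int(rng.integers(len(seq)))]


@dataclass
class _ReportPlan:
    offset: int
    # list of (concept, role, negated); role in
    # {debut, progression, remission, decoy, distractor}
    events: list[tuple[str, str, bool]] = field(default_factory=list)


def _render_report(rng: np.random.Generator, plan: _ReportPlan, report_id: str,
                   date: datetime.date) -> tuple[str, list[PlantedEvent]]:
    sentences: dict[str, list[str]] = {s: [] for s in _SECTION_ORDER}
    sentences["antecedentes"].append(_pick(rng, _FILLER["antecedentes"]))
    sentences["enfermedad_actual"].append(_pick(rng, _FILLER["enfermedad_actual"]))
    sentences["evolucion"].append(_pick(rng, _FILLER["evolucion"]))
    sentences["juicio_diagnostico"].append(_pick(rng, _FILLER["juicio_diagnostico"]))
    planted: list[PlantedEvent] = []
    ecg_used = False
    for concept, role, negated in plan.events:
        surface = _pick(rng, _SURFACES[concept])
        if role == "debut":
            section = _pick(rng, ("enfermedad_actual", "evolucion", "juicio_diagnostico"))
            tpl = _pick(rng, _AFFIRMED_DEBUT)
        elif role == "progression":
            if rng.random() < 0.5:
                section, tpl = "ecg", _pick(rng, _AFFIRMED_PROG_ECG)
            else:
                section = _pick(rng, ("evolucion", "juicio_diagnostico"))
                tpl = _pick(rng, _AFFIRMED_PROG)
        elif role == "remission":
            section, tpl = "ecg", _pick(rng, _AFFIRMED_REM_ECG)
        elif role == "decoy":
            section = _pick(rng, ("evolucion", "ecg"))
            tpl = _pick(rng, _NEGATED)
        elif role == "distractor":
            section = _pick(rng, ("evolucion", "ecg"))
            tpl = _pick(rng, _DISTRACTOR)
        else:  # pragma: no cover
            raise GenerationError(f"unknown role {role!r}")
        sentences[section].append(tpl.format(x=surface))
        if section == "ecg":
            ecg_used = True
        planted.append(PlantedEvent(concept, date, negated, report_id, section))
    if not sentences["ecg"] and not ecg_used:
        sentences["ecg"].append(_pick(rng, _FILLER["ecg"]))
    lines = []
    for sec in _SECTION_ORDER:
        if sentences[sec]:
            lines.append(f"{_HEADERS[sec]}: " + " ".join(sentences[sec]))
    return "\n".join(lines) + "\n", planted


# ---------------------------------------------------------------------------
# patient construction


def _n_reports(rng: np.random.Generator, params: GeneratorParams, minimum: int) -> int:
    n = 1 + int(rng.poisson(params.mean_reports_per_patient - 1.0))
    return max(n, minimum, 1)


def _unique_offset(offsets: set[int], rng: np.random.Generator, lo: int, hi: int) -> int:
    """Sample an integer in [lo, hi] not already used (inclusive bounds)."""
    for _ in range(1000):
        o = int(rng.integers(lo, hi + 1))
        if o not in offsets:
            offsets.add(o)
            return o
    raise GenerationError(f"cannot place a unique offset in [{lo}, {hi}]")


def generate_patient(
    seed: int,
    target_label: int,
    spec: TaskSpec,
    params: GeneratorParams,
    patient_id: str = "P00000",
    force_no_debut: bool = False,
) -> SyntheticPatient:
    """Construct one patient whose planted events realise ``target_label``.

    Deterministic for a fixed seed. ``force_no_debut`` restricts label -1 to
    the no-documented-debut variant (the only -1 variant for tasks without a
    remission concept).
    """
    if target_label not in (1, 0, -1):
        raise GenerationError(f"invalid target label {target_label!r}")
    rng = np.random.default_rng(seed)
    r0, _ = spec.remission_window_days
    p0, p1 = spec.progression_window_days

    needs_two = target_label == 1 or (target_label == 0 and spec.remission_concept is not None)
    n = _n_reports(rng, params, minimum=2 if needs_two else 1)

    no_debut = False
    if target_label == -1:
        no_debut = force_no_debut or spec.remission_concept is None or rng.random() < 0.5

    # --- plan offsets and decisive roles ------------------------------------
    used: set[int] = set()
    plans: list[_ReportPlan] = []
    debut_plan: Optional[_ReportPlan] = None
    if not (target_label == -1 and no_debut):
        used.add(0)
        debut_plan = _ReportPlan(0, [(spec.debut_concept, "debut", False)])
        plans.append(debut_plan)

    n_rest = n - len(plans)
    # optional single pre-debut filler report
    if debut_plan is not None and n_rest >= (2 if needs_two else 1) and rng.random() < 0.3:
        plans.append(_ReportPlan(-_unique_offset(used, rng, 10, 300)))
        # note: negative offsets stored positive in `used`; collisions with
        # positive offsets are harmless (dates differ), uniqueness is cosmetic
        n_rest -= 1

    contrary_report: Optional[_ReportPlan] = None
    if target_label == 1:
        off = _unique_offset(used, rng, p0, p1)
        prog = _ReportPlan(off, [(spec.progression_concept, "progression", False)])
        plans.append(prog)
        n_rest -= 1
        if rng.random() < params.contrary_ecg_rate:
            contrary_report = prog
        if (spec.remission_concept is not None and n_rest >= 1 and p0 - 1 >= r0
                and rng.random() < 0.5):
            # realistic arc: early return to sinus rhythm, later recurrence
            plans.append(_ReportPlan(_unique_offset(used, rng, r0, p0 - 1),
                                     [(spec.remission_concept, "remission", False)]))
            n_rest -= 1
    elif target_label == 0 and spec.remission_concept is not None:
        # mostly an early return to sinus rhythm, sometimes documented later
        hi = p0 - 1 if rng.random() < 0.7 else p1
        plans.append(_ReportPlan(_unique_offset(used, rng, r0, max(hi, r0)),
                                 [(spec.remission_concept, "remission", False)]))
        n_rest -= 1

    # filler reports: cumulative gaps from the debut, interleaving freely
    # with (and possibly extending past) the decisive reports
    gap_lo, gap_hi = params.report_gap_days
    cursor = 0
    for _ in range(n_rest):
        cursor += int(rng.integers(gap_lo, gap_hi + 1))
        while cursor in used:
            cursor += 1
        used.add(cursor)
        plans.append(_ReportPlan(cursor))

    # --- label-preserving perturbations -------------------------------------
    for plan in plans:
        if rng.random() < params.negation_rate:
            plan.events.append((spec.debut_concept, "decoy", True))
        if rng.random() < params.distractor_rate and OTHER_ARRHYTHMIA != spec.debut_concept:
            plan.events.append((OTHER_ARRHYTHMIA, "distractor", False))
    if contrary_report is not None and spec.remission_concept is not None:
        contrary_report.events.append((spec.remission_concept, "remission", False))

    # --- render -------------------------------------------------------------
    plans.sort(key=lambda p: p.offset)
    base = datetime.date(2015, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 1400)))
    reports: list[DischargeReport] = []
    events: list[PlantedEvent] = []
    for i, plan in enumerate(plans):
        rid = f"{patient_id}-r{i:02d}"
        date = base + datetime.timedelta(days=plan.offset)
        text, planted = _render_report(rng, plan, rid, date)
        reports.append(DischargeReport(report_id=rid, date=date, text=text))
        events.extend(planted)

    gold = gold_from_planted(events, spec)
    if gold != target_label:
        raise GenerationError(
            f"internal inconsistency: planted events imply {gold}, wanted {target_label}")
    history = build_timeline(
        PatientHistory(patient_id=patient_id, reports=reports, gold_label=gold))
    return SyntheticPatient(history=history, gold_label=gold, planted_events=events)


def generate_cohort(params: GeneratorParams, spec: TaskSpec) -> list[SyntheticPatient]:
    """Seeded cohort: labels are a multinomial draw of ``class_mix``."""
    rng = np.random.default_rng(params.seed)
    labels = rng.choice(np.array([1, 0, -1]), size=params.n_patients, p=list(params.class_mix))
    cohort = []
    for i, label in enumerate(labels):
        child_seed = int(rng.integers(0, _MAX_SEED))
        cohort.append(generate_patient(child_seed, int(label), spec, params,
                                       patient_id=f"P{i:05d}"))
    return cohort


ADVERSARIAL_KINDS = ("negation", "other_arrhythmia", "contrary_ecg")


def generate_adversarial(
    kind: str,
    n: int,
    seed: int,
    spec: Optional[TaskSpec] = None,
    params: Optional[GeneratorParams] = None,
) -> list[SyntheticPatient]:
    """Probe cohorts that mislead keyword-matching labelers.

    * ``negation``: every report carries negated disease mentions; any
      in-window mention of the disease is under a negation trigger (gold 0
      or -1).
    * ``other_arrhythmia``: affirmed distractor arrhythmias (flutter,
      ventricular tachycardia, ...) in every report; gold 0 or -1.
    * ``contrary_ecg``: one progression-window report holds both an AF ECG
      and a sinus-rhythm ECG; the in-window episode is real, gold 1.
    """
    if kind not in ADVERSARIAL_KINDS:
        raise ValueError(f"kind must be one of {ADVERSARIAL_KINDS}, got {kind!r}")
    spec = spec if spec is not None else af_progression()
    params = params if params is not None else default_params(spec)
    if kind == "negation":
        params = replace(params, negation_rate=1.0, distractor_rate=0.0, contrary_ecg_rate=0.0)
        targets = [0, -1]
    elif kind == "other_arrhythmia":
        params = replace(params, negation_rate=0.0, distractor_rate=1.0, contrary_ecg_rate=0.0)
        targets = [0, -1]
    else:
        params = replace(params, negation_rate=0.0, distractor_rate=0.0, contrary_ecg_rate=1.0)
        targets = [1]
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        target = targets[i % len(targets)]
        child_seed = int(rng.integers(0, _MAX_SEED))
        out.append(generate_patient(child_seed, target, spec, params,
                                    patient_id=f"ADV-{kind}-{i:04d}",
                                    force_no_debut=(target == -1)))
    return out


# ---------------------------------------------------------------------------
# per-step gold (for stepwise outcome analysis)


def step_gold(patient: SyntheticPatient, spec: TaskSpec,
              style: str = "rule") -> dict[tuple[str, str], str]:
    """Expected per-(report, step) decisions implied by the planted events.

    ``style="rule"`` mirrors the rule-pipeline trace (binary progression and
    remission checks per report). ``style="onset"`` mirrors the onset-guided
    3-class step 2 (YES in-window progression / NO sinus-rhythm evidence /
    UNKNOWN neither; binary for tasks without a remission concept). Both
    start with the chronological debut_search.
    """
    from .temporal import (DEBUT_SEARCH, PROGRESSION_CHECK, REMISSION_CHECK,
                           WindowClass, classify_window)

    by_report: dict[str, list[PlantedEvent]] = {}
    for e in patient.planted_events:
        by_report.setdefault(e.report_id, []).append(e)

    def _affirmed(rid: str, concept: str) -> bool:
        return any(not e.negated and e.section not in _EXCLUDED and e.concept == concept
                   for e in by_report.get(rid, ()))

    gold: dict[tuple[str, str], str] = {}
    debut_date = None
    for report in patient.history.reports:
        rid = report.report_id
        if debut_date is None:
            hit = _affirmed(rid, spec.debut_concept)
            gold[(rid, DEBUT_SEARCH)] = "YES" if hit else "NO"
            if hit:
                debut_date = report.date
            continue
        window = classify_window(debut_date, report.date, spec)
        prog = window is WindowClass.PROGRESSION_WINDOW and _affirmed(rid, spec.progression_concept)
        in_rem = window in (WindowClass.REMISSION_WINDOW, WindowClass.PROGRESSION_WINDOW)
        rem = (spec.remission_concept is not None and in_rem
               and _affirmed(rid, spec.remission_concept))
        if style == "rule":
            gold[(rid, PROGRESSION_CHECK)] = "YES" if prog else "NO"
            if spec.remission_concept is not None:
                gold[(rid, REMISSION_CHECK)] = "YES" if rem else "NO"
        elif style == "onset":
            if prog:
                gold[(rid, PROGRESSION_CHECK)] = "YES"
            elif rem:
                gold[(rid, PROGRESSION_CHECK)] = "NO"
            elif spec.remission_concept is None:
                gold[(rid, PROGRESSION_CHECK)] = "NO"
            else:
                gold[(rid, PROGRESSION_CHECK)] = "UNKNOWN"
        else:
            raise ValueError(f"style must be 'rule' or 'onset', got {style!r}")
    return gold
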