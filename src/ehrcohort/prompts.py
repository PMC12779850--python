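"""Prompt templating, date rendering, and strict output parsing.

Prompt bodies live as YAML data files (one per language, slot-compatible) so
users can substitute their own. Output parsing is deliberately strict: a
backend reply is valid only if, after normalization, it consists of exactly
one allowed label token — a correct answer buried inside prose still counts
as a format error, which measures instruction following, not just accuracy.
"""

from __future__ import annotations

import datetime
import re
import string
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .nlp import fold
from .records import days_between

YES = "YES"
NO = "NO"
UNKNOWN = "UNKNOWN"
FORMAT_ERROR = "FORMAT_ERROR"

THREE_CLASS = (YES, NO, UNKNOWN)
TWO_CLASS = (YES, NO)

STRATEGY_STEPS = (
    "concatenation",
    "summarization_worker",
    "summarization_manager",
    "onset_debut",
    "onset_progression",
    "chronology_remission",
    "chronology_progression",
)

#: slots each step's body must reference
REQUIRED_SLOTS = {
    "concatenation": {"report_blocks", "disease", "label_set"},
    "summarization_worker": {"summary", "report_block", "disease"},
    "summarization_manager": {"summary", "disease", "label_set"},
    "onset_debut": {"report_block", "disease"},
    "onset_progression": {"date_fragment", "report_block", "disease", "label_set"},
    "chronology_remission": {"date_fragment", "report_block", "disease"},
    "chronology_progression": {"date_fragment", "report_block", "disease", "label_set"},
}

DISEASE_NAMES = {
    ("af_progression", "es"): "fibrilación auricular (FA)",
    ("af_progression", "en"): "atrial fibrillation (AF)",
    ("hf_decompensation", "es"): "insuficiencia cardíaca (IC)",
    ("hf_decompensation", "en"): "heart failure (HF)",
}

LABEL_WORDS = {
    ("es", YES): "Sí",
    ("es", NO): "No",
    ("es", UNKNOWN): "Desconocido",
    ("en", YES): "Yes",
    ("en", NO): "No",
    ("en", UNKNOWN): "Unknown",
}


def label_set_phrase(allowed: Sequence[str], language: str) -> str:
    words = [LABEL_WORDS[(language, a)] for a in allowed]
    sep = " o " if language == "es" else " or "
    return ", ".join(words[:-1]) + sep + words[-1] if len(words) > 1 else words[0]


_SLOT_RE = re.compile(r"{(\w+)}")


@dataclass(frozen=True)
class PromptTemplate:
    strategy: str
    language: str
    body: str
    date_mode: Optional[str] = None

    def __post_init__(self) -> None:
        slots = set(_SLOT_RE.findall(self.body))
        missing = REQUIRED_SLOTS.get(self.strategy, set()) - slots
        if missing:
            raise ValueError(f"template {self.strategy}/{self.language} lacks slots {sorted(missing)}")

    def render(self, **slots: str) -> str:
        return self.body.format(**slots)


@lru_cache(maxsize=4)
def load_templates(language: str = "es") -> dict[str, PromptTemplate]:
    """Built-in prompt set for one language, keyed by strategy step."""
    if language not in ("es", "en"):
        raise ValueError(f"language must be 'es' or 'en', got {language!r}")
    path = resources.files("ehrcohort.data").joinpath(f"prompts_{language}.yaml")
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {step: PromptTemplate(step, language, body) for step, body in raw.items()}


# ---------------------------------------------------------------------------
# date rendering

_MONTHS_EN = ("January", "February", "March", "April", "May", "June", "July",
              "August", "September", "October", "November", "December")
_MONTHS_ES = ("enero", "febrero", "marzo", "abril", "mayo", "junio", "julio",
              "agosto", "septiembre", "octubre", "noviembre", "diciembre")

DATE_MODES = ("num", "nl", "dur")


def format_date(d: datetime.date, mode: str, language: str) -> str:
    """One date in numeric (2018-08-11) or written (August 11, 2018) form."""
    if mode == "num":
        return d.isoformat()
    if mode == "nl":
        if language == "es":
            return f"{d.day} de {_MONTHS_ES[d.month - 1]} de {d.year}"
        return f"{_MONTHS_EN[d.month - 1]} {d.day}, {d.year}"
    raise ValueError(f"format_date handles modes 'num' and 'nl', got {mode!r}")


def render_date(debut: datetime.date, report: datetime.date, mode: str, language: str) -> str:
    """The temporal fragment of a step-2 prompt.

    ``num``/``nl`` give the debut and current-report dates explicitly; ``dur``
    gives only the elapsed offset ("Time since debut: 18 days").
    """
    if mode == "dur":
        n = days_between(debut, report)
        if language == "es":
            return f"Tiempo desde el debut: {n} días"
        return f"Time since debut: {n} days"
    if mode not in ("num", "nl"):
        raise ValueError(f"date mode must be one of {DATE_MODES}, got {mode!r}")
    d, r = format_date(debut, mode, language), format_date(report, mode, language)
    if language == "es":
        return f"Fecha del debut: {d}\nFecha del informe actual: {r}"
    return f"Debut date: {d}\nCurrent report date: {r}"


# ---------------------------------------------------------------------------
# output parsing

@dataclass
class LabelResponse:
    """One parsed backend reply."""

    raw: str
    parsed: str  # YES / NO / UNKNOWN / FORMAT_ERROR
    scores: Optional[Mapping[str, float]] = None
    margin: Optional[float] = None


_TOKEN_MAP = {"yes": YES, "si": YES, "no": NO, "unknown": UNKNOWN, "desconocido": UNKNOWN}
_STRIP_CHARS = string.whitespace + string.punctuation + "¡¿«»“”'’"


def parse_label(raw: str, allowed: Sequence[str] = THREE_CLASS,
                language: Optional[str] = None) -> LabelResponse:
    """Strict label parsing.

    Normalization: diacritic fold, lowercase, strip surrounding whitespace
    and punctuation. The result must equal exactly one allowed label token
    ("sí"/"yes", "no", "desconocido"/"unknown"); anything longer — even text
    that contains the correct label — is a FORMAT_ERROR. ``language`` is
    informational; the synonym table covers both languages.
    """
    norm = fold(raw).strip(_STRIP_CHARS)
    label = _TOKEN_MAP.get(norm)
    if label is not None and label in allowed:
        return LabelResponse(raw=raw, parsed=label)
    return LabelResponse(raw=raw, parsed=FORMAT_ERROR)


def collect_margins(responses: Sequence[LabelResponse]) -> list[float]:
    """Margins of the scored responses, in order; unscored steps are omitted."""
    return [r.margin for r in responses if r.margin is not None]
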