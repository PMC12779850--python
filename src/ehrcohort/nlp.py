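"""Deterministic text stages: section segmentation, concept mention
extraction, and negation detection for Spanish discharge reports.

These are lightweight rule/lexicon implementations of the usual
section-identifier + medical-entity-recognition + negation stack. The
contract (sections in, mentions with assertion status out) is what the rest
of the pipeline depends on; statistical implementations can be substituted
behind the same functions.

Conventions: character offsets are 0-based half-open; all matching is case-
and diacritic-insensitive via a length-preserving character fold, so spans
always index the original text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .records import DischargeReport

OTROS = "otros"


def fold(text: str) -> str:
    """Lowercase, diacritic-stripped copy of *text* with identical length."""
    out = []
    for ch in text:
        base = unicodedata.normalize("NFD", ch)[0]
        low = base.lower()
        out.append(low if len(low) == 1 else base)
    return "".join(out)


@dataclass(frozen=True)
class Section:
    """A named slice of a report; spans partition the full text."""

    name: str
    start: int
    end: int


@dataclass(frozen=True)
class ClinicalMention:
    """One concept hit with its span, section, and assertion status."""

    concept: str
    surface: str
    start: int
    end: int
    section: str
    negated: bool


def _load_yaml(name: str) -> dict:
    with resources.files("ehrcohort.data").joinpath(name).open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def default_section_headers() -> dict[str, tuple[str, ...]]:
    raw = _load_yaml("section_headers_es.yaml")
    return {k: tuple(v) for k, v in raw.items()}


@lru_cache(maxsize=None)
def default_lexicon() -> dict[str, tuple[str, ...]]:
    raw = _load_yaml("lexicon_es.yaml")
    return {k: tuple(v) for k, v in raw["concepts"].items()}


@lru_cache(maxsize=None)
def default_negation_config() -> tuple[tuple[tuple[str, ...], ...], frozenset[str]]:
    raw = _load_yaml("negation_es.yaml")
    triggers = tuple(tuple(t.split()) for t in raw["triggers"])
    return triggers, frozenset(raw["scope_breakers"])


def _phrase_pattern(phrase: str) -> str:
    # whitespace in a phrase matches any whitespace run; anchors avoid
    # matching inside longer words (e.g. "fa" inside "grafa")
    body = re.escape(phrase).replace(r"\ ", r"\s+")
    return rf"(?<!\w){body}(?!\w)"


@lru_cache(maxsize=8)
def _header_regex(headers_key: tuple[tuple[str, tuple[str, ...]], ...]) -> tuple[re.Pattern, dict[str, str]]:
    alts: list[tuple[str, str]] = []  # (surface, canonical)
    for canonical, surfaces in headers_key:
        for s in surfaces:
            alts.append((s, canonical))
    alts.sort(key=lambda p: -len(p[0]))
    pattern = "(?m)^[ \\t]*(" + "|".join(re.escape(s) for s, _ in alts) + ")[ \\t]*:"
    return re.compile(pattern), {s: c for s, c in alts}


def segment_sections(text: str, headers: dict[str, tuple[str, ...]] | None = None) -> list[Section]:
    """Split a report into named sections by header lines.

    Headers are matched case/diacritic-insensitively at line starts followed
    by a colon; a section runs from its header to the next header. Text
    before the first header (or all text when no header matches) becomes
    ``otros``. The returned spans are disjoint, ordered, and cover the whole
    text; the empty string yields no sections.
    """
    if not text:
        return []
    headers = headers if headers is not None else default_section_headers()
    regex, surface_to_canonical = _header_regex(tuple(sorted(headers.items())))
    folded = fold(text)
    hits = [(m.start(), surface_to_canonical[m.group(1)]) for m in regex.finditer(folded)]
    sections: list[Section] = []
    if not hits or hits[0][0] > 0:
        first = hits[0][0] if hits else len(text)
        sections.append(Section(OTROS, 0, first))
    for i, (start, name) in enumerate(hits):
        end = hits[i + 1][0] if i + 1 < len(hits) else len(text)
        sections.append(Section(name, start, end))
    return sections


@lru_cache(maxsize=8)
def _compiled_lexicon(lexicon_key: tuple[tuple[str, tuple[str, ...]], ...]) -> list[tuple[re.Pattern, str]]:
    compiled = []
    for concept, phrases in lexicon_key:
        for phrase in phrases:
            compiled.append((re.compile(_phrase_pattern(phrase)), concept))
    return compiled


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_SENTENCE_BREAK = frozenset(".;!?\n")


def detect_negation(
    mention_start: int,
    text: str,
    window_tokens: int = 5,
    triggers: tuple[tuple[str, ...], ...] | None = None,
    scope_breakers: frozenset[str] | None = None,
) -> bool:
    """NegEx-style pre-mention negation check.

    True iff a trigger phrase occurs within ``window_tokens`` tokens before
    the mention, inside the same sentence, with the scope not interrupted by
    a clause/contrast cue ("pero", "aunque", ",", ";").
    """
    if triggers is None or scope_breakers is None:
        d_triggers, d_breakers = default_negation_config()
        triggers = triggers if triggers is not None else d_triggers
        scope_breakers = scope_breakers if scope_breakers is not None else d_breakers
    folded = fold(text)
    sent_start = 0
    for i in range(mention_start - 1, -1, -1):
        if folded[i] in _SENTENCE_BREAK:
            sent_start = i + 1
            break
    pre_tokens = _TOKEN_RE.findall(folded[sent_start:mention_start])
    scope: list[str] = []
    for tok in reversed(pre_tokens):
        if tok in scope_breakers:
            break
        scope.append(tok)
        if len(scope) >= window_tokens:
            break
    scope.reverse()
    for trig in triggers:
        n = len(trig)
        for i in range(len(scope) - n + 1):
            if tuple(scope[i : i + n]) == trig:
                return True
    return False


def extract_mentions(
    report: DischargeReport,
    lexicon: dict[str, tuple[str, ...]] | None = None,
    window_tokens: int = 5,
    apply_negation: bool = True,
) -> list[ClinicalMention]:
    """All non-overlapping, longest-first concept matches in a report.

    The report is segmented on demand (cached on ``report.sections``); each
    mention carries its section and, unless ``apply_negation`` is false, its
    negation status.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    if report.sections is None:
        report.sections = segment_sections(report.text)
    folded = fold(report.text)
    candidates: list[tuple[int, int, str]] = []
    for pattern, concept in _compiled_lexicon(tuple(sorted(lexicon.items()))):
        for m in pattern.finditer(folded):
            candidates.append((m.start(), m.end(), concept))
    # longest-first at equal starts, then greedy left-to-right non-overlap
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[ClinicalMention] = []
    last_end = -1
    for start, end, concept in candidates:
        if start < last_end:
            continue
        section = OTROS
        for sec in report.sections:
            if sec.start <= start < sec.end:
                section = sec.name
                break
        negated = (
            detect_negation(start, report.text, window_tokens=window_tokens)
            if apply_negation
            else False
        )
        mentions.append(
            ClinicalMention(
                concept=concept,
                surface=report.text[start:end],
                start=start,
                end=end,
                section=section,
                negated=negated,
            )
        )
        last_end = end
    return mentions
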