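"""Task definitions: which concepts define debut / progression / remission and
the day windows within which they count.

Window conventions (fixed day arithmetic: 1 week = 7 d, 1 month = 30 d,
2 years = 730 d):

* remission window is half-open ``[start, end)`` and its end coincides with
  the progression window start;
* progression window is closed ``[start, end]`` so evidence dated exactly on
  either boundary day counts.

Both are stored per task so alternative conventions stay configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

# Concept identifiers shared across the package.
AF = "AF"
SINUS_RHYTHM = "SINUS_RHYTHM"
CARDIOVERSION = "CARDIOVERSION"
ABLATION = "ABLATION"
HF = "HF"
OTHER_ARRHYTHMIA = "OTHER_ARRHYTHMIA"

CONCEPTS = (AF, SINUS_RHYTHM, CARDIOVERSION, ABLATION, HF, OTHER_ARRHYTHMIA)


@dataclass(frozen=True)
class TaskSpec:
    """Disease definition for one cohort-selection task.

    ``remission_concept`` may be ``None`` (heart-failure decompensation has no
    "return to normal" concept: non-decompensation is the absence of any new
    episode after a documented debut).
    """

    name: str
    debut_concept: str
    progression_concept: str
    remission_concept: Optional[str]
    remission_window_days: tuple[int, int]  # half-open [start, end)
    progression_window_days: tuple[int, int]  # closed [start, end]
    label_names: Mapping[int, str] = field(
        default_factory=lambda: {1: "Progression", 0: "Non-progression", -1: "Unknown"}
    )

    def __post_init__(self) -> None:
        r0, r1 = self.remission_window_days
        p0, p1 = self.progression_window_days
        for b in (r0, r1, p0, p1):
            if not isinstance(b, int) or b < 0:
                raise ValueError(f"{self.name}: window bounds must be non-negative integers")
        if p0 < r0:
            raise ValueError(f"{self.name}: progression window must not start before remission window")
        if r1 != p0:
            raise ValueError(f"{self.name}: remission window end must equal progression window start")
        if p1 < p0:
            raise ValueError(f"{self.name}: empty progression window")


def af_progression() -> TaskSpec:
    """Atrial-fibrillation progression.

    Progression = recurrence or permanence of AF 1 month to 2 years after the
    first documented AF episode; return to sinus rhythm is assessed from 1 day
    after the debut.
    """
    return TaskSpec(
        name="af_progression",
        debut_concept=AF,
        progression_concept=AF,
        remission_concept=SINUS_RHYTHM,
        remission_window_days=(1, 30),
        progression_window_days=(30, 730),
        label_names={1: "Progression", 0: "Non-progression", -1: "Unknown"},
    )


def hf_decompensation() -> TaskSpec:
    """Heart-failure decompensation.

    Decompensation = a new HF episode 1 week to 2 years after the HF debut;
    non-decompensation = a debut with no later episode; -1 = no documented
    debut in any report.
    """
    return TaskSpec(
        name="hf_decompensation",
        debut_concept=HF,
        progression_concept=HF,
        remission_concept=None,
        remission_window_days=(1, 7),
        progression_window_days=(7, 730),
        label_names={1: "Decompensation", 0: "Non-decompensation", -1: "No-debut"},
    )


_BUILTIN = {"af_progression": af_progression, "hf_decompensation": hf_decompensation}


def get_task(name: str) -> TaskSpec:
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise KeyError(f"unknown task {name!r}; available: {sorted(_BUILTIN)}") from None
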