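"""Evaluation: accuracy, macro-F1, format-error tally, Cohen's kappa,
confusion matrices, stepwise outcome taxonomy, temporality audit, and
margin-based uncertainty summaries.

Format errors are a fourth prediction outcome: they count as wrong in
accuracy and as recall misses for their gold class, but stay out of the
3x3 confusion matrix and are tallied separately. F1 is macro-averaged
(unweighted over the classes 1/0/-1) because the unknown class is a
first-class outcome and the classes are imbalanced; ``average="weighted"``
is available for comparison.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .temporal import (PROGRESSION_CHECK, REMISSION_CHECK, CohortLabel,
                       Decision, WindowClass)

CLASSES = (1, 0, -1)

CORRECT_WHOLE_HISTORY = "CORRECT_WHOLE_HISTORY"
CORRECT_FINAL_DECISION = "CORRECT_FINAL_DECISION"
INCORRECT = "INCORRECT"


def _value(pred: Union[CohortLabel, int, None]) -> Optional[int]:
    return pred.value if isinstance(pred, CohortLabel) else pred


@dataclass
class EvalReport:
    n: int
    accuracy: float
    macro_f1: float
    weighted_f1: float
    format_errors: int
    confusion: dict  # (gold, pred) -> count, over non-format-error predictions
    per_class_f1: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "format_errors": self.format_errors,
            "per_class_f1": {str(k): v for k, v in self.per_class_f1.items()},
            "confusion": {f"{g}->{p}": c for (g, p), c in sorted(self.confusion.items())},
        }


def score(pred: Mapping[str, Union[CohortLabel, int, None]],
          gold: Mapping[str, int]) -> EvalReport:
    """Score patient-level predictions against gold labels.

    Patient id sets must match exactly; a mismatch raises with the symmetric
    difference. Accuracy is the exact-match proportion over all gold
    patients, with format errors counted wrong.
    """
    missing = set(gold) ^ set(pred)
    if missing:
        raise ValueError(f"patient id mismatch between pred and gold: {sorted(missing)}")
    n = len(gold)
    confusion: Counter = Counter()
    format_errors = 0
    correct = 0
    for pid, g in gold.items():
        p = _value(pred[pid])
        if p is None:
            format_errors += 1
            continue
        confusion[(g, p)] += 1
        if p == g:
            correct += 1
    accuracy = correct / n if n else 0.0

    per_class_f1: dict[int, float] = {}
    support: dict[int, int] = {}
    for c in CLASSES:
        tp = confusion[(c, c)]
        predicted_c = sum(v for (g, p), v in confusion.items() if p == c)
        gold_c = sum(1 for g in gold.values() if g == c)  # format errors are misses
        support[c] = gold_c
        precision = tp / predicted_c if predicted_c else 0.0
        recall = tp / gold_c if gold_c else 0.0
        per_class_f1[c] = (2 * precision * recall / (precision + recall)
                           if precision + recall else 0.0)
    macro_f1 = sum(per_class_f1.values()) / len(CLASSES)
    weighted_f1 = (sum(per_class_f1[c] * support[c] for c in CLASSES) / n) if n else 0.0
    return EvalReport(n=n, accuracy=accuracy, macro_f1=macro_f1, weighted_f1=weighted_f1,
                      format_errors=format_errors, confusion=dict(confusion),
                      per_class_f1=per_class_f1)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` comes from the product of the two annotators' marginals. The
    degenerate case ``p_e == 1`` (both annotators constant on the same
    category) is defined as 1.0 when observed agreement is also perfect, and
    raises otherwise.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"length mismatch: {len(labels_a)} vs {len(labels_b)}")
    n = len(labels_a)
    if n == 0:
        raise ValueError("kappa needs at least one item")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    categories = set(ca) | set(cb)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in categories)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 but observed is not")
    return (p_o - p_e) / (1.0 - p_e)


def stepwise_outcomes(
    pred: Mapping[str, CohortLabel],
    gold: Mapping[str, int],
    oracle_steps: Mapping[str, Mapping[tuple[str, str], str]],
) -> tuple[Counter, int]:
    """Classify each patient's run against per-step gold decisions.

    CORRECT_WHOLE_HISTORY: final label correct and every recorded step
    decision matches the per-step gold. CORRECT_FINAL_DECISION: final label
    correct despite >=1 step error. INCORRECT: final label wrong (format
    errors included). Patients with no per-step gold are skipped; the second
    return value counts them.
    """
    taxonomy: Counter = Counter()
    skipped = 0
    for pid, label in pred.items():
        steps = oracle_steps.get(pid)
        if steps is None:
            skipped += 1
            continue
        final_ok = label.value is not None and label.value == gold[pid]
        if not final_ok:
            taxonomy[INCORRECT] += 1
            continue
        all_ok = True
        for record in label.trace:
            if record.decision is Decision.SKIPPED:
                continue
            key = (record.report_id, record.step)
            expected = steps.get(key)
            if expected is not None and record.decision.value != expected:
                all_ok = False
                break
        taxonomy[CORRECT_WHOLE_HISTORY if all_ok else CORRECT_FINAL_DECISION] += 1
    return taxonomy, skipped


#: windows in which a YES decision is temporally legitimate, per step
_ALLOWED_WINDOWS = {
    PROGRESSION_CHECK: {WindowClass.PROGRESSION_WINDOW},
    REMISSION_CHECK: {WindowClass.REMISSION_WINDOW, WindowClass.PROGRESSION_WINDOW},
}

TEMPORAL_RESPECTED = "temporal_relation_respected"
TEMPORAL_IGNORED = "temporal_relation_ignored"


def temporality_audit(pred: Mapping[str, CohortLabel]) -> dict[str, int]:
    """Count step decisions that used evidence outside its legitimate window.

    A step "ignores" temporality when it answers YES on a report whose window
    does not license that answer (e.g. progression fired on a pre-debut or
    beyond-2-years report). Only steps carrying window information are
    audited.
    """
    counts = {TEMPORAL_RESPECTED: 0, TEMPORAL_IGNORED: 0}
    for label in pred.values():
        for record in label.trace:
            if record.window is None or record.step not in _ALLOWED_WINDOWS:
                continue
            if record.decision is Decision.SKIPPED:
                continue
            if record.decision is Decision.YES and \
                    record.window not in _ALLOWED_WINDOWS[record.step]:
                counts[TEMPORAL_IGNORED] += 1
            else:
                counts[TEMPORAL_RESPECTED] += 1
    return counts


@dataclass
class GroupStats:
    n: int
    mean: float
    sd: float


@dataclass
class MarginSummary:
    correct: Optional[GroupStats]
    incorrect: Optional[GroupStats]
    flagged: list[str]


def _stats(values: list[float]) -> Optional[GroupStats]:
    if not values:
        return None
    mean = sum(values) / len(values)
    if len(values) < 2:
        return GroupStats(n=1, mean=mean, sd=0.0)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return GroupStats(n=len(values), mean=mean, sd=math.sqrt(var))


def margin_summary(margins: Mapping[str, Sequence[float]],
                   correct: Mapping[str, bool],
                   threshold: float = 3.0) -> MarginSummary:
    """Log-likelihood margin summary by correctness group.

    A patient's margin is the mean over its scored steps; patients with *any*
    step margin below ``threshold`` are flagged for manual review.
    """
    by_group: dict[bool, list[float]] = {True: [], False: []}
    flagged: list[str] = []
    for pid, ms in margins.items():
        if not ms:
            continue
        by_group[bool(correct[pid])].append(sum(ms) / len(ms))
        if any(m < threshold for m in ms):
            flagged.append(pid)
    return MarginSummary(correct=_stats(by_group[True]),
                         incorrect=_stats(by_group[False]),
                         flagged=sorted(flagged))
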