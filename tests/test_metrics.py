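"""Scoring, Cohen's kappa, stepwise outcome taxonomy, temporality audit,
and margin summaries."""

import random
from collections import Counter

import pytest

from ehrcohort import (CohortLabel, cohens_kappa, margin_summary, score,
                       stepwise_outcomes, temporality_audit)
from ehrcohort.metrics import (CORRECT_FINAL_DECISION, CORRECT_WHOLE_HISTORY,
                               INCORRECT, TEMPORAL_IGNORED, TEMPORAL_RESPECTED)
from ehrcohort.temporal import (DEBUT_SEARCH, PROGRESSION_CHECK, Decision,
                                StepRecord, WindowClass)


def _labels(values):
    return {f"p{i}": v for i, v in enumerate(values)}


class TestScore:
    def test_perfect_agreement(self):
        gold = _labels([1, 0, -1, 1, 0, -1, 1, 0, -1, 1])
        report = score(gold, gold)
        assert report.accuracy == 1.0 and report.macro_f1 == 1.0
        assert report.format_errors == 0

    def test_all_format_errors(self):
        gold = _labels([1, 0, -1, 1])
        pred = {k: CohortLabel(value=None, format_error=True) for k in gold}
        report = score(pred, gold)
        assert report.accuracy == 0.0
        assert report.format_errors == 4
        assert report.confusion == {}

    def test_hand_computed_confusion(self):
        # gold x pred counts: (1,1):2 (1,0):1 (0,0):3 (-1,-1):4
        gold = _labels([1, 1, 1, 0, 0, 0, -1, -1, -1, -1])
        pred = _labels([1, 1, 0, 0, 0, 0, -1, -1, -1, -1])
        report = score(pred, gold)
        assert report.accuracy == pytest.approx(0.9)
        # class 1: P=1, R=2/3, F1=0.8; class 0: P=3/4, R=1, F1=6/7; class -1: 1
        assert report.per_class_f1[1] == pytest.approx(0.8)
        assert report.per_class_f1[0] == pytest.approx(6 / 7)
        assert report.per_class_f1[-1] == pytest.approx(1.0)
        assert report.macro_f1 == pytest.approx((0.8 + 6 / 7 + 1.0) / 3)

    def test_id_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="p9"):
            score(_labels([1]), {"p0": 1, "p9": 0})

    def test_matches_sklearn_macro_f1(self):
        from sklearn.metrics import f1_score
        rng = random.Random(0)
        for _ in range(50):
            n = rng.randint(3, 40)
            gold = [rng.choice([1, 0, -1]) for _ in range(n)]
            pred = [rng.choice([1, 0, -1]) for _ in range(n)]
            report = score(_labels(pred), _labels(gold))
            expected = f1_score(gold, pred, labels=[1, 0, -1], average="macro",
                                zero_division=0)
            assert report.macro_f1 == pytest.approx(expected)


class TestCohensKappa:
    def test_identical_vectors(self):
        assert cohens_kappa([1, 0, -1, 1], [1, 0, -1, 1]) == 1.0

    def test_worked_examples(self):
        assert cohens_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)
        assert cohens_kappa([1, 1, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_degenerate_marginals(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0
        with pytest.raises(ValueError):
            cohens_kappa([], [])
        with pytest.raises(ValueError):
            cohens_kappa([1, 1], [1])

    def test_matches_brute_force_contingency(self):
        """Closed form == full contingency-table computation, and == sklearn."""
        from sklearn.metrics import cohen_kappa_score
        rng = random.Random(42)
        for _ in range(1000):
            n = rng.randint(2, 30)
            a = [rng.choice([1, 0, -1]) for _ in range(n)]
            b = [rng.choice([1, 0, -1]) for _ in range(n)]
            cats = sorted(set(a) | set(b))
            table = {(x, y): 0 for x in cats for y in cats}
            for x, y in zip(a, b):
                table[(x, y)] += 1
            p_o = sum(table[(c, c)] for c in cats) / n
            p_e = sum((sum(table[(c, y)] for y in cats) / n)
                      * (sum(table[(x, c)] for x in cats) / n) for c in cats)
            if p_e >= 1.0 - 1e-15:
                continue
            expected = (p_o - p_e) / (1 - p_e)
            assert cohens_kappa(a, b) == pytest.approx(expected)
            assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))


def _traced(value, steps):
    return CohortLabel(value=value, trace=steps)


class TestStepwiseOutcomes:
    GOLD_STEPS = {("a", DEBUT_SEARCH): "YES", ("b", PROGRESSION_CHECK): "YES"}

    def test_all_steps_correct(self):
        pred = {"p": _traced(1, [StepRecord("a", DEBUT_SEARCH, Decision.YES),
                                 StepRecord("b", PROGRESSION_CHECK, Decision.YES)])}
        taxonomy, skipped = stepwise_outcomes(pred, {"p": 1}, {"p": self.GOLD_STEPS})
        assert taxonomy == Counter({CORRECT_WHOLE_HISTORY: 1}) and skipped == 0

    def test_intermediate_error_with_correct_final(self):
        gold_steps = {("a", DEBUT_SEARCH): "YES", ("b", PROGRESSION_CHECK): "YES",
                      ("c", PROGRESSION_CHECK): "NO"}
        pred = {"p": _traced(1, [StepRecord("a", DEBUT_SEARCH, Decision.YES),
                                 StepRecord("b", PROGRESSION_CHECK, Decision.YES),
                                 StepRecord("c", PROGRESSION_CHECK, Decision.YES)])}
        taxonomy, _ = stepwise_outcomes(pred, {"p": 1}, {"p": gold_steps})
        assert taxonomy == Counter({CORRECT_FINAL_DECISION: 1})

    def test_wrong_final_is_incorrect_regardless_of_steps(self):
        pred = {"p": _traced(0, [StepRecord("a", DEBUT_SEARCH, Decision.YES)])}
        taxonomy, _ = stepwise_outcomes(pred, {"p": 1}, {"p": self.GOLD_STEPS})
        assert taxonomy == Counter({INCORRECT: 1})

    def test_missing_step_gold_skips_patient(self):
        pred = {"p": _traced(1, [])}
        taxonomy, skipped = stepwise_outcomes(pred, {"p": 1}, {})
        assert skipped == 1 and sum(taxonomy.values()) == 0

    def test_counts_sum_to_n(self, af_cohort, af_spec):
        from ehrcohort import label_patient_rule_based, step_gold
        pred = {p.history.patient_id: label_patient_rule_based(p.history, af_spec)
                for p in af_cohort}
        gold = {p.history.patient_id: p.gold_label for p in af_cohort}
        steps = {p.history.patient_id: step_gold(p, af_spec) for p in af_cohort}
        taxonomy, skipped = stepwise_outcomes(pred, gold, steps)
        assert sum(taxonomy.values()) + skipped == len(af_cohort)
        assert taxonomy[CORRECT_WHOLE_HISTORY] == len(af_cohort)


class TestTemporalityAudit:
    def test_yes_on_post_window_report_is_ignored_temporality(self):
        pred = {"p": _traced(1, [StepRecord("r", PROGRESSION_CHECK, Decision.YES,
                                            WindowClass.POST_WINDOW, 800)])}
        assert temporality_audit(pred) == {TEMPORAL_RESPECTED: 0, TEMPORAL_IGNORED: 1}

    def test_in_window_decisions_are_respected(self):
        pred = {"p": _traced(0, [
            StepRecord("r", PROGRESSION_CHECK, Decision.NO,
                       WindowClass.PROGRESSION_WINDOW, 60),
            StepRecord("s", PROGRESSION_CHECK, Decision.YES,
                       WindowClass.PROGRESSION_WINDOW, 90)])}
        assert temporality_audit(pred) == {TEMPORAL_RESPECTED: 2, TEMPORAL_IGNORED: 0}

    def test_chronology_runs_have_zero_ignored(self, af_cohort, af_oracle, af_spec):
        from ehrcohort import run_chronology_guided
        pred = {p.history.patient_id:
                run_chronology_guided(p.history, af_oracle, spec=af_spec).label
                for p in af_cohort}
        assert temporality_audit(pred)[TEMPORAL_IGNORED] == 0


class TestMarginSummary:
    def test_constant_margins(self):
        s = margin_summary({"a": [4.0, 4.0], "b": [4.0]}, {"a": True, "b": True})
        assert s.correct.mean == pytest.approx(4.0) and s.correct.sd == 0.0
        assert s.incorrect is None

    def test_group_means(self):
        s = margin_summary({"a": [4.0, 4.0], "b": [2.0, 2.0]},
                           {"a": True, "b": False}, threshold=3.0)
        assert s.correct.mean == pytest.approx(4.0)
        assert s.incorrect.mean == pytest.approx(2.0)
        assert s.flagged == ["b"]

    def test_low_margin_flagging(self):
        s = margin_summary({"a": [3.5, 0.23]}, {"a": False})
        assert s.flagged == ["a"]
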