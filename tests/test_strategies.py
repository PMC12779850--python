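"""Orchestration strategies over deterministic backends: call-count
contracts, oracle equivalence, window exclusion, and the long-context
contrast between concatenation and onset-guided prompting."""

import datetime

import pytest

from ehrcohort import (DischargeReport, OracleBackend, PatientHistory,
                       ScriptedBackend, TruncatingBackend, VerboseBackend,
                       default_params, generate_cohort, run_chronology_guided,
                       run_concatenation, run_onset_guided, run_summarization)
from ehrcohort.prompts import FORMAT_ERROR
from ehrcohort.temporal import DEBUT_SEARCH, Decision


class TestCallCounts:
    def test_summarization_makes_n_plus_one_calls(self, af_cohort, af_oracle, af_spec):
        for p in af_cohort[:10]:
            run = run_summarization(p.history, af_oracle, spec=af_spec)
            n = len(p.history.reports)
            assert run.n_calls == n + 1
            assert len(run.summaries) == n

    def test_concatenation_makes_one_call(self, af_cohort, af_oracle, af_spec):
        run = run_concatenation(af_cohort[0].history, af_oracle, spec=af_spec)
        assert run.n_calls == 1

    def test_empty_history_needs_no_backend(self, af_spec):
        boom = ScriptedBackend(lambda prompt: (_ for _ in ()).throw(AssertionError))
        h = PatientHistory("empty")
        assert run_concatenation(h, boom, spec=af_spec).label.value == -1
        assert run_summarization(h, boom, spec=af_spec).label.value == -1

    def test_debut_scan_stops_at_first_yes(self, af_cohort, af_oracle, af_spec):
        for p in af_cohort[:10]:
            run = run_onset_guided(p.history, af_oracle, spec=af_spec)
            debut_steps = [s for s in run.label.trace if s.step == DEBUT_SEARCH]
            if any(s.decision is Decision.YES for s in debut_steps):
                assert debut_steps[-1].decision is Decision.YES
                assert all(s.decision is Decision.NO for s in debut_steps[:-1])

    def test_no_debut_means_no_step2_calls(self, af_spec):
        backend = ScriptedBackend(lambda prompt: "No")
        h = PatientHistory("p", [
            DischargeReport("a", datetime.date(2018, 1, 1), "EVOLUCIÓN: estable.\n"),
            DischargeReport("b", datetime.date(2018, 3, 1), "EVOLUCIÓN: estable.\n"),
        ])
        run = run_onset_guided(h, backend, spec=af_spec)
        assert run.label.value == -1
        assert all(r.step == DEBUT_SEARCH for r in run.prompt_log)


class TestOracleEquivalence:
    @pytest.mark.parametrize("date_mode", ["num", "nl", "dur"])
    @pytest.mark.parametrize("language", ["es", "en"])
    def test_onset_guided_recovers_gold(self, af_cohort, af_oracle, af_spec,
                                        date_mode, language):
        from ehrcohort import load_templates
        templates = load_templates(language)
        for p in af_cohort:
            run = run_onset_guided(p.history, af_oracle, templates=templates,
                                   spec=af_spec, date_mode=date_mode, language=language)
            assert run.label.value == p.gold_label

    def test_chronology_guided_recovers_gold(self, af_cohort, af_oracle, af_spec):
        for p in af_cohort:
            run = run_chronology_guided(p.history, af_oracle, spec=af_spec)
            assert run.label.value == p.gold_label

    def test_concat_and_summarization_recover_gold(self, af_cohort, af_oracle, af_spec):
        for p in af_cohort:
            assert run_concatenation(p.history, af_oracle, spec=af_spec).label.value \
                == p.gold_label
            assert run_summarization(p.history, af_oracle, spec=af_spec).label.value \
                == p.gold_label

    def test_hf_strategies_recover_gold(self, hf_spec):
        cohort = generate_cohort(default_params(hf_spec, n_patients=40, seed=21), hf_spec)
        oracle = OracleBackend(cohort, hf_spec)
        for p in cohort:
            assert run_onset_guided(p.history, oracle, spec=hf_spec).label.value \
                == p.gold_label
            assert run_chronology_guided(p.history, oracle, spec=hf_spec).label.value \
                == p.gold_label


class TestWindowExclusion:
    def test_post_window_reports_never_reach_the_backend(self, af_cohort, af_oracle,
                                                         af_spec):
        for p in af_cohort:
            run = run_chronology_guided(p.history, af_oracle, spec=af_spec)
            dates = {r.report_id: r.date for r in p.history.reports}
            debut_yes = [s for s in run.label.trace
                         if s.step == DEBUT_SEARCH and s.decision is Decision.YES]
            if not debut_yes:
                continue
            debut_date = dates[debut_yes[0].report_id]
            for record in run.prompt_log:
                if record.step == DEBUT_SEARCH:
                    continue
                offset = (dates[record.report_id] - debut_date).days
                assert 1 <= offset <= 730


class TestLongContextContrast:
    def test_truncation_breaks_concatenation_but_not_onset(self, af_spec):
        params = default_params(af_spec, n_patients=200, seed=31,
                                mean_reports_per_patient=6.0)
        cohort = generate_cohort(params, af_spec)
        oracle = OracleBackend(cohort, af_spec)
        truncated = TruncatingBackend(oracle, max_chars=900)

        def prog_index(p):
            affirmed = [e for e in p.planted_events if not e.negated]
            debut = min(e.date for e in affirmed if e.concept == af_spec.debut_concept)
            order = [r.report_id for r in p.history.reports]
            hits = [order.index(e.report_id) for e in affirmed
                    if e.concept == af_spec.progression_concept
                    and 30 <= (e.date - debut).days <= 730]
            return min(hits)

        late = [p for p in cohort if p.gold_label == 1 and prog_index(p) >= 2]
        assert len(late) >= 20
        concat_acc = sum(
            run_concatenation(p.history, truncated, spec=af_spec).label.value == 1
            for p in late) / len(late)
        onset_acc = sum(
            run_onset_guided(p.history, oracle, spec=af_spec).label.value == 1
            for p in late) / len(late)
        assert concat_acc < 0.5
        assert onset_acc == 1.0


class TestFormatErrorPolicy:
    def test_verbose_replies_become_format_errors(self, af_cohort, af_oracle, af_spec):
        verbose = VerboseBackend(af_oracle)
        for p in af_cohort[:15]:
            run = run_concatenation(p.history, verbose, spec=af_spec)
            assert run.label.format_error and run.label.value is None
            assert run.prompt_log[0].parsed == FORMAT_ERROR
            # the correct label IS inside the text; it still does not count
            assert any(w in run.prompt_log[0].raw for w in ("Yes", "No", "Unknown"))

    def test_step_level_format_error_marks_patient(self, af_spec):
        replies = iter(["Sí", "La respuesta es Sí"])
        backend = ScriptedBackend(lambda prompt: next(replies))
        h = PatientHistory("p", [
            DischargeReport("a", datetime.date(2018, 1, 1),
                            "ENFERMEDAD ACTUAL: Primer episodio de FA.\n"),
            DischargeReport("b", datetime.date(2018, 3, 1), "ECG: ritmo sinusal.\n"),
        ])
        run = run_onset_guided(h, backend, spec=af_spec)
        assert run.label.format_error


class TestMargins:
    def test_oracle_margins_propagate_to_trace(self, af_cohort, af_spec):
        oracle = OracleBackend(af_cohort, af_spec, margin=4.0)
        run = run_onset_guided(af_cohort[0].history, oracle, spec=af_spec)
        margins = [s.margin for s in run.label.trace if s.margin is not None]
        assert margins and all(m == pytest.approx(4.0) for m in margins)

    def test_margin_is_top_minus_second(self):
        from ehrcohort.prompts import LabelResponse, collect_margins
        r = LabelResponse(raw="Yes", parsed="YES",
                          scores={"YES": -1.0, "NO": -4.0, "UNKNOWN": -9.0})
        r.margin = sorted(r.scores.values(), reverse=True)[0] - \
            sorted(r.scores.values(), reverse=True)[1]
        assert r.margin == pytest.approx(3.0)
        tied = LabelResponse(raw="No", parsed="NO", margin=0.0)
        assert collect_margins([r, tied, LabelResponse(raw="?", parsed="FORMAT_ERROR")]) \
            == [3.0, 0.0]
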