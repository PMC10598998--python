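"""Session engine tests: stack navigation, validation, displayif, payloads."""

from __future__ import annotations

import pytest

from questmark import (
    AnswerValidationError,
    EngineConfig,
    ExpressionError,
    InvalidModule,
    QuestionRef,
    SessionNotFinished,
    SkipNotAllowed,
    StepCapExceeded,
    VersionMismatch,
    evaluate_displayif,
    finalize,
    load_session,
    parse_displayif,
    parse_module,
    payload_json,
    resolve_piping,
    run_script,
    save_session,
    skip_without_answer,
    start_session,
    submit_answer,
)
from conftest import run_with_path


class TestStartSession:
    def test_starts_at_first_question(self, module):
        assert start_session(module).current_id == "QUESTION_1"

    def test_end_only_module_is_immediately_finished(self):
        state = start_session(parse_module("[END] bye"))
        assert state.finished and state.current_id == "END"

    def test_displayif_false_at_start_skips_to_second(self):
        m = parse_module(
            "[Q1] gated <displayif equals(AGE, 63)>\n(1) x\n[Q2] shown\n(1) y\n[END] bye"
        )
        assert start_session(m, prefill={"AGE": 50}).current_id == "Q2"
        assert start_session(m, prefill={"AGE": 63}).current_id == "Q1"

    def test_invalid_module_refused(self):
        m = parse_module("[Q1] a\n(1) x -> NOWHERE\n[END] bye")
        with pytest.raises(InvalidModule):
            start_session(m)


class TestStackNavigation:
    def test_checkbox_pushes_pop_in_declaration_order(self, module, walkthrough_answers):
        path, _ = run_with_path(module, walkthrough_answers)
        assert path == ["QUESTION_1", "QUESTION_2", "DECON1", "TEMP", "END"]

    def test_radio_jump_is_immediate(self, module):
        path, _ = run_with_path(
            module, {"QUESTION_1": "2", "QUESTION_2": ["13"], "DECON1": "1", "DECON2": "rest"}
        )
        assert path == ["QUESTION_1", "QUESTION_2", "DECON1", "DECON2", "END"]

    def test_no_branch_pops_stack(self, module):
        path, _ = run_with_path(module, {"QUESTION_1": "2", "QUESTION_2": ["15"], "TEMP": 98})
        assert path == ["QUESTION_1", "QUESTION_2", "TEMP", "END"]

    def test_empty_stack_falls_through_in_document_order(self):
        m = parse_module("[Q1] a\n|__|\n[Q2] b\n|__|\n[END] bye")
        path, _ = run_with_path(m, {"Q1": "x", "Q2": "y"})
        assert path == ["Q1", "Q2", "END"]

    def test_default_next_pushed_even_for_radio_jump(self):
        # the default-next survives on the stack across a direct radio jump
        m = parse_module(
            "[Q1] a < -> Q3>\n(1) x -> Q2\n[Q2] b\n|__|\n[Q3] c\n|__|\n[END] bye"
        )
        path, _ = run_with_path(m, {"Q1": "1", "Q2": "b", "Q3": "c"})
        assert path == ["Q1", "Q2", "Q3", "END"]

    def test_step_cap_guards_cycles(self):
        m = parse_module("[A] a\n(1) x -> B\n[B] b\n(1) y -> A\n[END] bye")
        with pytest.raises(StepCapExceeded):
            run_script(m, {"A": "1", "B": "1"})


class TestAnswerValidation:
    @pytest.mark.parametrize("value", [90, 98, 120])
    def test_numeric_bounds_closed_interval(self, module, value):
        state = start_session(module)
        submit_answer(state, "2")
        submit_answer(state, ["15"])
        submit_answer(state, value)
        assert state.responses["TEMP"] == value

    @pytest.mark.parametrize("value", [89, 121])
    def test_numeric_out_of_bounds_rejected(self, module, value):
        state = start_session(module)
        submit_answer(state, "2")
        submit_answer(state, ["15"])
        with pytest.raises(AnswerValidationError):
            submit_answer(state, value)

    def test_unknown_radio_value_rejected(self, module):
        with pytest.raises(AnswerValidationError):
            submit_answer(start_session(module), "9")

    def test_unknown_checkbox_value_rejected(self, module):
        state = start_session(module)
        submit_answer(state, "2")
        with pytest.raises(AnswerValidationError):
            submit_answer(state, ["13", "99"])

    @pytest.mark.parametrize(
        "markup, good, bad",
        [
            ("[Q1] d\n|date|\n[END] e", "2024-02-29", "2023-02-29"),
            ("[Q1] t\n|tel|\n[END] e", "301-555-0134", "555-0134"),
            ("[Q1] s\n|SSN|\n[END] e", "987-65-4321", "987654321"),
        ],
    )
    def test_formatted_inputs(self, markup, good, bad):
        m = parse_module(markup)
        state = start_session(m)
        with pytest.raises(AnswerValidationError):
            submit_answer(state, bad)
        submit_answer(state, good)
        assert state.responses["Q1"] == good


class TestSkipping:
    def test_nr_target_routes_unanswered_question(self):
        m = parse_module("[Q1] a <#NR -> TEMP>\n(1) x\n[Q2] b\n|__|\n[TEMP] t\n|__|__|\n[END] e")
        state = start_session(m)
        skip_without_answer(state)
        assert state.current_id == "TEMP"
        assert "Q1" not in state.responses

    def test_skip_without_nr_falls_through(self, module):
        state = start_session(module)
        skip_without_answer(state)
        assert state.current_id == "QUESTION_2"

    def test_strict_config_requires_answers(self, module):
        state = start_session(module, config=EngineConfig(allow_skip=False))
        with pytest.raises(SkipNotAllowed):
            skip_without_answer(state)

    def test_skipping_everything_reaches_end(self, module):
        path, payload = run_with_path(module, {})
        assert path[-1] == "END" and payload == {}


class TestDisplayIf:
    def test_equals_with_recorded_response(self):
        e = parse_displayif("equals(DECON1, 1)")
        assert evaluate_displayif(e, {"DECON1": 1})
        assert not evaluate_displayif(e, {"DECON1": 0})

    def test_numeric_coercion_across_types(self):
        e = parse_displayif("equals(Q, 2)")
        assert evaluate_displayif(e, {"Q": "2"})

    def test_exists_unanswered_is_false(self):
        e = parse_displayif("exists(TEMP)")
        assert not evaluate_displayif(e, {})
        assert evaluate_displayif(e, {"TEMP": 98})

    def test_unanswered_comparison_is_false_not_error(self):
        assert not evaluate_displayif(parse_displayif("greaterThan(TEMP, 90)"), {})
        assert not evaluate_displayif(parse_displayif("notEquals(TEMP, 1)"), {})

    def test_walkthrough_conjunction(self):
        e = parse_displayif("and(equals(QUESTION_1, 2), greaterThan(TEMP, 90))")
        assert evaluate_displayif(e, {"QUESTION_1": 2, "TEMP": 98})
        assert not evaluate_displayif(e, {"QUESTION_1": 1, "TEMP": 98})

    def test_checkbox_answer_compares_by_membership(self):
        e = parse_displayif("equals(QUESTION_2, 13)")
        assert evaluate_displayif(e, {"QUESTION_2": [13, 15]})
        assert not evaluate_displayif(e, {"QUESTION_2": [15]})

    def test_type_mismatch_raises(self):
        with pytest.raises(ExpressionError):
            evaluate_displayif(parse_displayif("greaterThan(Q, 5)"), {"Q": "abc"})

    def test_prefill_fallback(self):
        e = parse_displayif("equals(AGE, 63)")
        assert evaluate_displayif(e, {}, {"AGE": 63})

    def test_displayif_false_question_recorded_nowhere(self):
        m = parse_module(
            "[Q1] a\n(1) yes\n(0) no\n"
            "[Q2] gated <displayif equals(Q1, 1)>\n|__|\n[END] bye"
        )
        path, payload = run_with_path(m, {"Q1": "0", "Q2": "never"})
        assert path == ["Q1", "END"] and payload == {"Q1": 0}


class TestPiping:
    def test_prefill_substitution(self):
        assert resolve_piping("You are {AGE} years old", {}, {"AGE": 63}) == "You are 63 years old"

    def test_no_placeholder_unchanged(self):
        assert resolve_piping("plain text", {}, {}) == "plain text"

    def test_response_wins_over_prefill_and_unresolved_stays(self):
        out = resolve_piping("{TEMP} and {MISSING}", {"TEMP": 98}, {"TEMP": 1})
        assert out == "98 and {MISSING}"


class TestFinalize:
    def test_walkthrough_payload(self, module, walkthrough_answers):
        payload = run_script(module, walkthrough_answers)
        assert payload == {"QUESTION_1": 2, "QUESTION_2": [13, 15], "DECON1": 0, "TEMP": 98}
        assert isinstance(payload["QUESTION_1"], int)
        assert payload["QUESTION_2"] == [13, 15]

    def test_end_only_module_empty_payload(self):
        assert run_script(parse_module("[END] bye"), {}) == {}

    @pytest.mark.parametrize(
        "raw, expected", [("007", "007"), ("0", 0), ("-5", -5), ("42", 42), ("4x", "4x")]
    )
    def test_numeric_typing_rule(self, raw, expected):
        m = parse_module("[Q1] code\n|__|\n[END] bye")
        assert run_script(m, {"Q1": raw}) == {"Q1": expected}

    def test_completion_hook_receives_payload(self, module, walkthrough_answers):
        seen = []
        run_script(module, walkthrough_answers, on_complete=seen.append)
        assert seen == [{"QUESTION_1": 2, "QUESTION_2": [13, 15], "DECON1": 0, "TEMP": 98}]

    def test_unfinished_session_refuses_finalize(self, module):
        with pytest.raises(SessionNotFinished):
            finalize(start_session(module))

    def test_canonical_json_is_sorted_and_compact(self, module, walkthrough_answers):
        payload = run_script(module, walkthrough_answers)
        assert payload_json(payload) == (
            '{"DECON1":0,"QUESTION_1":2,"QUESTION_2":[13,15],"TEMP":98}'
        )


class TestPersistence:
    def test_save_load_mid_session_continues_identically(self, module, walkthrough_answers):
        state = start_session(module)
        submit_answer(state, "2")
        submit_answer(state, ["13", "15"])
        resumed = load_session(save_session(state), module)
        assert resumed.current_id == state.current_id
        assert resumed.stack == state.stack
        submit_answer(resumed, "0")
        submit_answer(resumed, 98)
        assert finalize(resumed) == run_script(module, walkthrough_answers)

    def test_load_against_edited_module_rejected(self, module):
        doc = save_session(start_session(module))
        edited = parse_module("[Q1] changed\n(1) x\n[END] bye")
        with pytest.raises(VersionMismatch):
            load_session(doc, edited)

    def test_save_load_at_every_step_preserves_payload(self, module, walkthrough_answers):
        from questmark import load_session, save_session

        baseline = run_script(module, walkthrough_answers)
        state = start_session(module)
        while not state.finished:
            state = load_session(save_session(state), module)
            q = state.current_question
            if q.is_display_only:
                submit_answer(state, None)
            elif q.id in walkthrough_answers:
                submit_answer(state, walkthrough_answers[q.id])
            else:
                skip_without_answer(state)
        assert finalize(state) == baseline
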