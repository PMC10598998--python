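"""Session engine: stack-based skip-logic interpreter for Quest modules.

Navigation follows the markup's stack semantics.  Answering a question may
push pending question ids onto a LIFO stack:

* a selected radio option with an arrow transfers control to its target
  directly;
* a multi-select (checkbox) answer pushes the declared default-next target
  first, then the selected options' arrow targets in reverse declaration
  order, so the targets are visited in declaration order;
* the default-next target, when declared, is pushed on every submission;
* with nothing to jump to, the next question is popped from the stack, and
  when the stack is empty it is the document-order successor.

A question whose ``displayif`` guard evaluates false at arrival is skipped
transparently (nothing recorded); ``<#NR -> QID>`` routes participants who
answer nothing.  A configurable step cap guards against cyclic markup.

On completion, :func:`finalize` serializes the responses to the JSON payload
contract: scalars for radio/input answers, lists (in option declaration
order) for checkbox answers, with digit-only values emitted as numbers, and
invokes any registered completion hooks with the payload — the library
equivalent of the renderer's completion callback.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Any, Callable

from .errors import (
    AnswerValidationError,
    ExpressionError,
    InvalidModule,
    SessionNotFinished,
    SkipNotAllowed,
    StepCapExceeded,
    VersionMismatch,
)
from .model import (
    END_ID,
    DisplayIfExpr,
    InputKind,
    Question,
    QuestionnaireModule,
    QuestionRef,
)
from .parser import serialize_module

_INT_RE = re.compile(r"-?(0|[1-9][0-9]*)")
_TEL_RE = re.compile(r"\d{3}-\d{3}-\d{4}")
_SSN_RE = re.compile(r"\d{3}-\d{2}-\d{4}")
_PIPE_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_#]*)\}")

SESSION_FORMAT = "questmark-session/1"


@dataclass
class EngineConfig:
    """Tunable session behaviour.

    ``step_cap`` defaults to 10x the question count; ``allow_skip`` permits
    skipping questions that declare no ``#NR`` target.
    """

    step_cap: int | None = None
    allow_skip: bool = True

    def cap_for(self, module: QuestionnaireModule) -> int:
        return self.step_cap if self.step_cap is not None else 10 * max(len(module), 1)


@dataclass
class SessionState:
    """Interpreter state for one participant session."""

    module: QuestionnaireModule
    current_id: str | None = None
    stack: list[str] = field(default_factory=list)
    responses: dict[str, Any] = field(default_factory=dict)
    prefill: dict[str, Any] = field(default_factory=dict)
    finished: bool = False
    steps: int = 0
    config: EngineConfig = field(default_factory=EngineConfig)
    hooks: list[Callable[[dict[str, Any]], None]] = field(default_factory=list, compare=False)

    @property
    def current_question(self) -> Question | None:
        if self.current_id is None:
            return None
        return self.module.get(self.current_id)


def module_hash(module: QuestionnaireModule) -> str:
    """Content hash of the canonical markup (used to pin saved sessions)."""
    return hashlib.sha256(serialize_module(module).encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# displayif evaluation and piping
# ---------------------------------------------------------------------------

_MISSING = object()


def _lookup(ref: QuestionRef, responses: dict[str, Any], prefill: dict[str, Any]) -> Any:
    if ref.id in responses:
        return responses[ref.id]
    if ref.id in prefill:
        return prefill[ref.id]
    return _MISSING


def _as_number(value: Any) -> float | None:
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return None
    return None


def _resolve_arg(arg: Any, responses: dict[str, Any], prefill: dict[str, Any]) -> Any:
    if isinstance(arg, QuestionRef):
        return _lookup(arg, responses, prefill)
    return arg


def _scalar_equal(a: Any, b: Any) -> bool:
    na, nb = _as_number(a), _as_number(b)
    if na is not None and nb is not None:
        return na == nb
    return str(a) == str(b)


def evaluate_displayif(
    expr: DisplayIfExpr,
    responses: dict[str, Any],
    prefill: dict[str, Any] | None = None,
) -> bool:
    """Evaluate a displayif guard against recorded responses and prefill.

    References to unanswered questions make comparisons false rather than
    raising; a checkbox answer (a list) compares by membership.
    """
    prefill = prefill or {}
    func = expr.func
    if func in ("and", "or"):
        results = []
        for sub in expr.args:
            if not isinstance(sub, DisplayIfExpr):
                raise ExpressionError(f"{func} arguments must be expressions, got {sub!r}")
            value = evaluate_displayif(sub, responses, prefill)
            if func == "and" and not value:
                return False
            if func == "or" and value:
                return True
            results.append(value)
        return func == "and"
    if func == "exists":
        ref = expr.args[0]
        if not isinstance(ref, QuestionRef):
            raise ExpressionError("exists takes a question reference")
        return _lookup(ref, responses, prefill) is not _MISSING

    lhs = _resolve_arg(expr.args[0], responses, prefill)
    rhs = _resolve_arg(expr.args[1], responses, prefill)
    if isinstance(lhs, DisplayIfExpr) or isinstance(rhs, DisplayIfExpr):
        raise ExpressionError(f"{func} does not take nested expressions")
    if lhs is _MISSING or rhs is _MISSING:
        return False

    if func in ("equals", "notEquals"):
        if isinstance(lhs, (list, tuple)):
            hit = any(_scalar_equal(v, rhs) for v in lhs)
        elif isinstance(rhs, (list, tuple)):
            hit = any(_scalar_equal(lhs, v) for v in rhs)
        else:
            hit = _scalar_equal(lhs, rhs)
        return hit if func == "equals" else not hit
    if func in ("greaterThan", "lessThan"):
        na, nb = _as_number(lhs), _as_number(rhs)
        if na is None or nb is None:
            raise ExpressionError(f"{func} requires numeric operands, got {lhs!r}, {rhs!r}")
        return na > nb if func == "greaterThan" else na < nb
    raise ExpressionError(f"unknown displayif function {func!r}")


def resolve_piping(
    text: str,
    responses: dict[str, Any],
    prefill: dict[str, Any] | None = None,
) -> str:
    """Substitute ``{KEY}`` placeholders from responses, then prefill.

    Unresolvable placeholders are left verbatim; list answers join with
    a comma.
    """
    prefill = prefill or {}

    def sub(m: re.Match[str]) -> str:
        key = m.group(1)
        if key in responses:
            value = responses[key]
        elif key in prefill:
            value = prefill[key]
        else:
            return m.group(0)
        if isinstance(value, (list, tuple)):
            return ", ".join(str(v) for v in value)
        return str(value)

    return _PIPE_RE.sub(sub, text)


# ---------------------------------------------------------------------------
# session lifecycle
# ---------------------------------------------------------------------------

def _is_displayable(q: Question, state: SessionState) -> bool:
    if q.displayif is None:
        return True
    return evaluate_displayif(q.displayif, state.responses, state.prefill)


def _pop_or_successor(state: SessionState, from_id: str) -> str | None:
    if state.stack:
        return state.stack.pop()
    return state.module.successor(from_id)


def _tick(state: SessionState) -> None:
    state.steps += 1
    if state.steps > state.config.cap_for(state.module):
        raise StepCapExceeded(
            f"session exceeded step cap {state.config.cap_for(state.module)}; "
            "the module's skip logic likely cycles"
        )


def _arrive(state: SessionState, next_id: str | None) -> None:
    """Move to *next_id*, transparently skipping displayif-false questions."""
    while True:
        if next_id is None:
            state.current_id = None
            state.finished = True
            return
        question = state.module.get(next_id)
        if question is None:
            raise InvalidModule(f"navigation reached undefined question id {next_id!r}")
        if not _is_displayable(question, state):
            _tick(state)
            next_id = _pop_or_successor(state, next_id)
            continue
        state.current_id = next_id
        if question.id == END_ID and question.is_display_only:
            state.finished = True
        return


def start_session(
    module: QuestionnaireModule,
    prefill: dict[str, Any] | None = None,
    config: EngineConfig | None = None,
    on_complete: Callable[[dict[str, Any]], None] | None = None,
    validate: bool = True,
) -> SessionState:
    """Open a session at the first displayable question.

    Raises :class:`InvalidModule` when the module has validation errors
    (pass ``validate=False`` to bypass the gate, e.g. for experiments).
    """
    if validate:
        from .validator import validate_module

        errors = [d for d in validate_module(module) if d.severity == "error"]
        if errors:
            raise InvalidModule(
                "module has validation errors: " + "; ".join(str(e) for e in errors)
            )
    state = SessionState(module=module, prefill=dict(prefill or {}), config=config or EngineConfig())
    if on_complete is not None:
        state.hooks.append(on_complete)
    if not module.questions:
        state.finished = True
        return state
    _arrive(state, module.questions[0].id)
    return state


# ---------------------------------------------------------------------------
# answer validation
# ---------------------------------------------------------------------------

def _validate_input_value(q: Question, f, value: Any) -> Any:
    if f.kind is InputKind.NUMERIC:
        num = _as_number(value)
        if num is None:
            raise AnswerValidationError(f"{q.id}: expected a numeric answer, got {value!r}")
        if f.min is not None and num < f.min:
            raise AnswerValidationError(f"{q.id}: {num:g} is below the minimum {f.min:g}")
        if f.max is not None and num > f.max:
            raise AnswerValidationError(f"{q.id}: {num:g} is above the maximum {f.max:g}")
        return int(num) if num == int(num) else num
    text = str(value)
    if f.kind is InputKind.DATE:
        try:
            date.fromisoformat(text)
        except ValueError:
            raise AnswerValidationError(f"{q.id}: {text!r} is not an ISO date (YYYY-MM-DD)") from None
    elif f.kind is InputKind.TEL:
        if not _TEL_RE.fullmatch(text):
            raise AnswerValidationError(f"{q.id}: {text!r} is not a phone number (ddd-ddd-dddd)")
    elif f.kind is InputKind.SSN:
        if not _SSN_RE.fullmatch(text):
            raise AnswerValidationError(f"{q.id}: {text!r} is not an SSN (ddd-dd-dddd)")
    return text


def _normalize_answer(q: Question, answer: Any) -> tuple[Any, list[str]]:
    """Validate *answer* against *q*'s response spec.

    Returns ``(recorded_value, selected_option_values)``.
    """
    if q.is_radio:
        if isinstance(answer, (list, tuple)):
            raise AnswerValidationError(f"{q.id}: single-select question takes one value")
        token = str(answer)
        values = [o.value for o in q.options]
        if token not in values:
            raise AnswerValidationError(
                f"{q.id}: {token!r} is not among the option values {values}"
            )
        return token, [token]
    if q.is_checkbox:
        if not isinstance(answer, (list, tuple, set)):
            answer = [answer]
        tokens = {str(a) for a in answer}
        values = [o.value for o in q.options]
        unknown = tokens - set(values)
        if unknown:
            raise AnswerValidationError(
                f"{q.id}: unknown option values {sorted(unknown)}; valid: {values}"
            )
        ordered = [v for v in values if v in tokens]  # option declaration order
        return ordered, ordered
    if q.inputs:
        if len(q.inputs) == 1:
            if isinstance(answer, (list, tuple)):
                raise AnswerValidationError(f"{q.id}: input question takes one value")
            return _validate_input_value(q, q.inputs[0], answer), []
        if not isinstance(answer, (list, tuple)) or len(answer) != len(q.inputs):
            raise AnswerValidationError(
                f"{q.id}: expected {len(q.inputs)} values for {len(q.inputs)} input fields"
            )
        return [
            _validate_input_value(q, f, v) for f, v in zip(q.inputs, answer)
        ], []
    if answer is not None:
        raise AnswerValidationError(f"{q.id}: display-only question takes no answer")
    return None, []


# ---------------------------------------------------------------------------
# navigation
# ---------------------------------------------------------------------------

def next_question_id(
    state: SessionState, question: Question, selected_values: list[str]
) -> str | None:
    """Compute the next question id, updating the stack.

    The default-next target is pushed unconditionally; a selected radio
    arrow transfers directly; checkbox arrows are pushed in reverse
    declaration order so they pop in declaration order; otherwise the stack
    is popped, falling back to the document-order successor.
    """
    _tick(state)
    if question.default_next is not None:
        state.stack.append(question.default_next)
    if question.is_radio and selected_values:
        option = next(o for o in question.options if o.value == selected_values[0])
        if option.jump_target is not None:
            return option.jump_target
    elif question.is_checkbox:
        targets = [
            o.jump_target
            for o in question.options
            if o.value in selected_values and o.jump_target is not None
        ]
        state.stack.extend(reversed(targets))
    return _pop_or_successor(state, question.id)


def submit_answer(state: SessionState, answer: Any) -> SessionState:
    """Record *answer* for the current question and advance the session."""
    if state.finished:
        raise SessionNotFinished("session already finished")
    question = state.current_question
    if question is None:
        raise SessionNotFinished("no current question")
    recorded, selected = _normalize_answer(question, answer)
    if recorded is not None:
        state.responses[question.id] = recorded
    if question.id == END_ID:
        state.finished = True
        return state
    _arrive(state, next_question_id(state, question, selected))
    return state


def skip_without_answer(state: SessionState) -> SessionState:
    """Advance past the current question without recording a response."""
    if state.finished:
        raise SessionNotFinished("session already finished")
    question = state.current_question
    if question is None:
        raise SessionNotFinished("no current question")
    if question.id == END_ID:
        state.finished = True
        return state
    if question.nr_target is not None:
        _tick(state)
        if question.default_next is not None:
            state.stack.append(question.default_next)
        _arrive(state, question.nr_target)
        return state
    if not state.config.allow_skip and not question.is_display_only:
        raise SkipNotAllowed(f"{question.id} is required and declares no #NR target")
    _arrive(state, next_question_id(state, question, []))
    return state


# ---------------------------------------------------------------------------
# completion payload
# ---------------------------------------------------------------------------

def _json_scalar(value: Any) -> Any:
    if isinstance(value, bool) or not isinstance(value, str):
        return value
    if _INT_RE.fullmatch(value):
        return int(value)
    return value


def _json_value(value: Any) -> Any:
    if isinstance(value, (list, tuple)):
        return [_json_scalar(v) for v in value]
    return _json_scalar(value)


def finalize(state: SessionState) -> dict[str, Any]:
    """Serialize responses to the completion payload and fire hooks.

    Digit-only strings (no leading zeros) become numbers, so a code like
    ``"007"`` survives as a string while ``"98"`` is emitted as ``98``.
    """
    if not state.finished:
        raise SessionNotFinished(f"session is at {state.current_id}, not finished")
    payload = {qid: _json_value(v) for qid, v in state.responses.items()}
    for hook in state.hooks:
        hook(payload)
    return payload


def payload_json(payload: dict[str, Any]) -> str:
    """Canonical serialization: UTF-8, sorted keys."""
    return json.dumps(payload, sort_keys=True, ensure_ascii=False, separators=(",", ":"))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_session(state: SessionState) -> str:
    """Serialize a session to an opaque JSON document (resumability)."""
    doc = {
        "format": SESSION_FORMAT,
        "module_hash": module_hash(state.module),
        "current_id": state.current_id,
        "stack": list(state.stack),
        "responses": state.responses,
        "prefill": state.prefill,
        "finished": state.finished,
        "steps": state.steps,
        "step_cap": state.config.step_cap,
        "allow_skip": state.config.allow_skip,
    }
    return json.dumps(doc, sort_keys=True, ensure_ascii=False)


def load_session(document: str, module: QuestionnaireModule) -> SessionState:
    """Restore a session saved with :func:`save_session`.

    Raises :class:`VersionMismatch` when *module* differs from the module
    the session was saved against.
    """
    doc = json.loads(document)
    if doc.get("format") != SESSION_FORMAT:
        raise VersionMismatch(f"unknown session format {doc.get('format')!r}")
    if doc["module_hash"] != module_hash(module):
        raise VersionMismatch("session was saved against a different module version")
    return SessionState(
        module=module,
        current_id=doc["current_id"],
        stack=list(doc["stack"]),
        responses=dict(doc["responses"]),
        prefill=dict(doc["prefill"]),
        finished=doc["finished"],
        steps=doc["steps"],
        config=EngineConfig(step_cap=doc.get("step_cap"), allow_skip=doc.get("allow_skip", True)),
    )


# ---------------------------------------------------------------------------
# scripted replay
# ---------------------------------------------------------------------------

def run_script(
    module: QuestionnaireModule,
    answers: dict[str, Any],
    prefill: dict[str, Any] | None = None,
    config: EngineConfig | None = None,
    on_complete: Callable[[dict[str, Any]], None] | None = None,
) -> dict[str, Any]:
    """Replay a session non-interactively from an answer script.

    Each question encountered is answered from *answers* by id; questions
    absent from the script are skipped (via ``#NR`` routing when declared).
    Returns the finalized payload.
    """
    state = start_session(module, prefill=prefill, config=config, on_complete=on_complete)
    while not state.finished:
        qid = state.current_id
        assert qid is not None
        question = state.module[qid]
        if question.is_display_only:
            submit_answer(state, None)
        elif qid in answers:
            submit_answer(state, answers[qid])
        else:
            skip_without_answer(state)
    return finalize(state)
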