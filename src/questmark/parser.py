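"""Line-oriented parser for Quest questionnaire markup.

The grammar is deliberately simple and decidable line by line:

* A question block begins at any line whose first non-blank token is ``[ID]``
  where ``ID`` is a valid question id (capital first letter, then capitals,
  digits, underscores or ``#``).  Everything up to the next such line belongs
  to the block.
* ``(value) label`` is a radio (single-select) option, ``[value] label`` a
  checkbox (multi-select) option.  Option values may not be valid question
  ids — that restriction is what makes headers and checkbox options
  distinguishable.  An optional trailing ``-> QID`` arrow routes the session
  to ``QID`` when the option is selected.
* ``|__|`` is a text input, ``|__|__|`` a numeric input (optionally annotated
  ``min=<n> max=<n>``), and ``|date|`` / ``|tel|`` / ``|SSN|`` map to the
  corresponding HTML input types.
* Angle-bracket directives carry the skip logic: ``< -> QID>`` declares the
  default next question, ``<#NR -> QID>`` the no-response target, and
  ``<displayif func(...)>`` a guard expression.

Everything else in a block is question text; ``{KEY}`` pipe placeholders are
kept verbatim (substitution happens in the session engine).
"""

from __future__ import annotations

import re
from dataclasses import asdict
from typing import Any

from .errors import ParseError
from .model import (
    DisplayIfExpr,
    InputField,
    InputKind,
    OptionKind,
    Question,
    QuestionnaireModule,
    QuestionRef,
    ResponseOption,
)

_ID_RE = re.compile(r"[A-Z][A-Z0-9_#]*")
_HEADER_RE = re.compile(r"^\s*\[([A-Z][A-Z0-9_#]*)\]\s?(.*)$")
_OPTION_RE = re.compile(r"^\s*([(\[])([^()\[\]\s]+)([)\]])\s*(.*)$")
_ARROW_RE = re.compile(r"^(.*?)\s*->\s*(\S+)\s*$")
# the arrow token contains '>', so directive bodies admit '->' as a unit
_DIRECTIVE_RE = re.compile(r"<\s*(->|#NR|displayif)((?:->|[^<>])*)>")
_INPUT_RE = re.compile(r"^\s*(\|__\|__\||\|__\||\|date\||\|tel\||\|SSN\|)\s*(.*)$")
_MINMAX_RE = re.compile(r"(min|max)\s*=\s*(-?\d+(?:\.\d+)?)")

DISPLAYIF_FUNCS = {
    "equals": 2,
    "notEquals": 2,
    "greaterThan": 2,
    "lessThan": 2,
    "exists": 1,
    "and": None,  # variadic, >= 2
    "or": None,
}


def is_valid_question_id(token: str) -> bool:
    """True iff *token* is a well-formed question id.

    The first character must be a capital letter A-Z; the remaining
    characters may be capital letters, digits, underscores or ``#``.
    """
    return bool(token) and _ID_RE.fullmatch(token) is not None


def _number(token: str) -> int | float:
    try:
        return int(token)
    except ValueError:
        return float(token)


# ---------------------------------------------------------------------------
# displayif expression grammar (recursive descent)
# ---------------------------------------------------------------------------

class _ExprParser:
    """``func(arg, ...)`` with nested calls, refs, numbers and quoted strings."""

    def __init__(self, src: str, line: int):
        self.src = src
        self.pos = 0
        self.line = line

    def error(self, msg: str) -> ParseError:
        return ParseError(f"displayif: {msg} (at offset {self.pos} in {self.src!r})", self.line)

    def skip_ws(self) -> None:
        while self.pos < len(self.src) and self.src[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.src[self.pos] if self.pos < len(self.src) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def parse(self) -> DisplayIfExpr:
        expr = self.parse_call()
        self.skip_ws()
        if self.pos != len(self.src):
            raise self.error("trailing characters after expression")
        return expr

    def parse_call(self) -> DisplayIfExpr:
        self.skip_ws()
        m = re.compile(r"[A-Za-z_][A-Za-z0-9_]*").match(self.src, self.pos)
        if not m:
            raise self.error("expected function name")
        func = m.group(0)
        if func not in DISPLAYIF_FUNCS:
            raise self.error(f"unknown function {func!r}")
        self.pos = m.end()
        self.skip_ws()
        self.expect("(")
        args: list[Any] = []
        while True:
            self.skip_ws()
            if self.peek() == ")" and not args:
                break
            args.append(self.parse_arg())
            self.skip_ws()
            if self.peek() == ",":
                self.pos += 1
                continue
            break
        self.expect(")")
        arity = DISPLAYIF_FUNCS[func]
        if arity is None:
            if len(args) < 2:
                raise self.error(f"{func} takes at least 2 arguments, got {len(args)}")
        elif len(args) != arity:
            raise self.error(f"{func} takes exactly {arity} argument(s), got {len(args)}")
        return DisplayIfExpr(func=func, args=tuple(args))

    def parse_arg(self) -> Any:
        self.skip_ws()
        ch = self.peek()
        if ch in "\"'":
            quote = ch
            self.pos += 1
            start = self.pos
            while self.pos < len(self.src) and self.src[self.pos] != quote:
                self.pos += 1
            if self.pos >= len(self.src):
                raise self.error("unterminated string literal")
            lit = self.src[start:self.pos]
            self.pos += 1
            return lit
        m = re.compile(r"-?\d+(?:\.\d+)?").match(self.src, self.pos)
        if m:
            self.pos = m.end()
            return _number(m.group(0))
        m = re.compile(r"[A-Za-z_][A-Za-z0-9_#]*").match(self.src, self.pos)
        if m:
            token = m.group(0)
            save = self.pos
            self.pos = m.end()
            self.skip_ws()
            if self.peek() == "(":
                self.pos = save
                return self.parse_call()
            if is_valid_question_id(token):
                return QuestionRef(token)
            return token  # bare lowercase word: a string literal
        raise self.error("expected argument")


def parse_displayif(src: str, line: int = 0) -> DisplayIfExpr:
    """Parse a displayif guard expression such as ``equals(DECON1, 1)``."""
    return _ExprParser(src, line).parse()


# ---------------------------------------------------------------------------
# line-level pieces
# ---------------------------------------------------------------------------

def parse_response_line(line: str, lineno: int = 0) -> ResponseOption:
    """Parse one option line: ``(v) label [-> QID]`` or ``[v] label [-> QID]``."""
    m = _OPTION_RE.match(line)
    if not m:
        raise ParseError(f"not a response option line: {line!r}", lineno)
    open_b, value, close_b, rest = m.groups()
    if (open_b, close_b) == ("(", ")"):
        kind = OptionKind.RADIO
    elif (open_b, close_b) == ("[", "]"):
        kind = OptionKind.CHECKBOX
    else:
        raise ParseError(f"mismatched option brackets in {line!r}", lineno)
    if is_valid_question_id(value):
        raise ParseError(
            f"option value {value!r} is a valid question id; values may not be question ids",
            lineno,
        )
    jump: str | None = None
    am = _ARROW_RE.match(rest)
    if am:
        rest, jump = am.group(1), am.group(2)
        if not is_valid_question_id(jump):
            raise ParseError(f"arrow target {jump!r} is not a valid question id", lineno)
    return ResponseOption(kind=kind, value=value, label=rest.strip(), jump_target=jump)


def parse_directive(fragment: str, lineno: int = 0) -> tuple[str, Any]:
    """Parse the inside of one ``<...>`` directive.

    Returns ``("default_next", id)``, ``("nr_target", id)`` or
    ``("displayif", DisplayIfExpr)``.
    """
    body = fragment.strip()
    if body.startswith("->"):
        target = body[2:].strip()
        if not is_valid_question_id(target):
            raise ParseError(f"default-next target {target!r} is not a valid question id", lineno)
        return "default_next", target
    if body.startswith("#NR"):
        rest = body[3:].strip()
        if not rest.startswith("->"):
            raise ParseError(f"expected '->' after #NR in <{body}>", lineno)
        target = rest[2:].strip()
        if not is_valid_question_id(target):
            raise ParseError(f"#NR target {target!r} is not a valid question id", lineno)
        return "nr_target", target
    if body.startswith("displayif"):
        expr_src = body[len("displayif"):].strip()
        if expr_src.startswith("="):
            expr_src = expr_src[1:].strip()
        return "displayif", parse_displayif(expr_src, lineno)
    keyword = body.split(None, 1)[0] if body else ""
    raise ParseError(f"unknown directive keyword {keyword!r}", lineno)


def parse_input_field(token: str, lineno: int = 0) -> InputField:
    """Parse one pipe input token, e.g. ``|__|__| min=90 max=120``."""
    m = _INPUT_RE.match(token)
    if not m:
        raise ParseError(f"unknown input token {token.strip()!r}", lineno)
    pipe, rest = m.groups()
    kind = {
        "|__|": InputKind.TEXT,
        "|__|__|": InputKind.NUMERIC,
        "|date|": InputKind.DATE,
        "|tel|": InputKind.TEL,
        "|SSN|": InputKind.SSN,
    }[pipe]
    lo: int | float | None = None
    hi: int | float | None = None
    rest = rest.strip()
    if rest:
        if kind is not InputKind.NUMERIC:
            raise ParseError(f"min/max annotations only apply to numeric inputs: {token!r}", lineno)
        consumed = 0
        for mm in _MINMAX_RE.finditer(rest):
            if mm.group(1) == "min":
                lo = _number(mm.group(2))
            else:
                hi = _number(mm.group(2))
            consumed += len(mm.group(0))
        if consumed == 0 or _MINMAX_RE.sub("", rest).strip():
            raise ParseError(f"malformed min/max annotation: {rest!r}", lineno)
        if lo is not None and hi is not None and lo > hi:
            raise ParseError(f"min {lo} exceeds max {hi}", lineno)
    return InputField(kind=kind, min=lo, max=hi)


# ---------------------------------------------------------------------------
# module-level parsing
# ---------------------------------------------------------------------------

def _split_directives(line: str, lineno: int) -> tuple[str, list[tuple[str, Any]]]:
    """Pull all ``<...>`` directives out of a line; return the remainder."""
    directives: list[tuple[str, Any]] = []

    def grab(m: re.Match[str]) -> str:
        directives.append(parse_directive(m.group(1) + m.group(2), lineno))
        return " "

    remainder = _DIRECTIVE_RE.sub(grab, line)
    return remainder, directives


def parse_module(text: str, source_name: str = "<string>") -> QuestionnaireModule:
    """Parse Quest markup text into a :class:`QuestionnaireModule`.

    Raises :class:`ParseError` (with a line number) on duplicate ids,
    malformed blocks, content before the first header, mixed option kinds, or
    blocks mixing options with input fields.
    """
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    module = QuestionnaireModule(source_name=source_name)
    current: Question | None = None
    text_lines: list[str] = []

    def close_block() -> None:
        nonlocal current
        if current is None:
            return
        current.text = "\n".join(text_lines)
        if current.options and current.inputs:
            raise ParseError(
                f"question {current.id!r} mixes response options with input fields",
                current.source_line,
            )
        kinds = {o.kind for o in current.options}
        if len(kinds) > 1:
            raise ParseError(
                f"question {current.id!r} mixes radio and checkbox options",
                current.source_line,
            )
        current.position = len(module.questions)
        module.questions.append(current)
        module.index[current.id] = current.position
        current = None

    for lineno, raw in enumerate(text.split("\n"), start=1):
        header = _HEADER_RE.match(raw)
        if header:
            close_block()
            qid = header.group(1)
            if qid in module.index or (current is not None and current.id == qid):
                raise ParseError(f"duplicate question id {qid!r}", lineno)
            current = Question(id=qid, source_line=lineno)
            text_lines = []
            rest = header.group(2)
            if rest.strip():
                _consume_body_line(current, text_lines, rest, lineno)
            continue
        if not raw.strip():
            continue
        if current is None:
            raise ParseError("content before the first question header", lineno)
        _consume_body_line(current, text_lines, raw, lineno)

    close_block()
    return module


def _set_directive(q: Question, kind: str, value: Any, lineno: int) -> None:
    if getattr(q, kind) is not None:
        raise ParseError(f"question {q.id!r} declares {kind} more than once", lineno)
    setattr(q, kind, value)


def _consume_body_line(q: Question, text_lines: list[str], raw: str, lineno: int) -> None:
    remainder, directives = _split_directives(raw, lineno)
    for kind, value in directives:
        _set_directive(q, kind, value, lineno)
    line = remainder.strip()
    if not line:
        return
    if _OPTION_RE.match(line):
        q.options.append(parse_response_line(line, lineno))
    elif line.startswith("|"):
        q.inputs.append(parse_input_field(line, lineno))
    else:
        text_lines.append(line)


def parse_file(path: str) -> QuestionnaireModule:
    with open(path, encoding="utf-8") as fh:
        return parse_module(fh.read(), source_name=path)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _serialize_displayif(expr: DisplayIfExpr) -> str:
    parts = []
    for arg in expr.args:
        if isinstance(arg, DisplayIfExpr):
            parts.append(_serialize_displayif(arg))
        elif isinstance(arg, QuestionRef):
            parts.append(arg.id)
        elif isinstance(arg, str):
            parts.append(f'"{arg}"')
        else:
            parts.append(repr(arg))
    return f"{expr.func}({', '.join(parts)})"


def _serialize_input(f: InputField) -> str:
    token = {
        InputKind.TEXT: "|__|",
        InputKind.NUMERIC: "|__|__|",
        InputKind.DATE: "|date|",
        InputKind.TEL: "|tel|",
        InputKind.SSN: "|SSN|",
    }[f.kind]
    ann = []
    if f.min is not None:
        ann.append(f"min={f.min:g}")
    if f.max is not None:
        ann.append(f"max={f.max:g}")
    return " ".join([token, *ann])


def serialize_module(module: QuestionnaireModule) -> str:
    """Emit canonical markup such that ``parse(serialize(m))`` equals ``m``."""
    blocks: list[str] = []
    for q in module.questions:
        lines: list[str] = []
        text_lines = q.text.split("\n") if q.text else []
        head = f"[{q.id}]"
        if text_lines:
            head += f" {text_lines[0]}"
        lines.append(head)
        lines.extend(text_lines[1:])
        if q.displayif is not None:
            lines.append(f"<displayif {_serialize_displayif(q.displayif)}>")
        if q.default_next is not None:
            lines.append(f"< -> {q.default_next}>")
        if q.nr_target is not None:
            lines.append(f"<#NR -> {q.nr_target}>")
        for o in q.options:
            lb, rb = ("(", ")") if o.kind is OptionKind.RADIO else ("[", "]")
            opt = f"{lb}{o.value}{rb} {o.label}".rstrip()
            if o.jump_target:
                opt += f" -> {o.jump_target}"
            lines.append(opt)
        for f in q.inputs:
            lines.append(_serialize_input(f))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# AST export
# ---------------------------------------------------------------------------

def _displayif_to_obj(expr: DisplayIfExpr) -> dict[str, Any]:
    args: list[Any] = []
    for a in expr.args:
        if isinstance(a, DisplayIfExpr):
            args.append(_displayif_to_obj(a))
        elif isinstance(a, QuestionRef):
            args.append({"ref": a.id})
        else:
            args.append(a)
    return {"func": expr.func, "args": args}


def module_to_dict(module: QuestionnaireModule) -> dict[str, Any]:
    """JSON-serializable view of a parsed module (``quest ast``)."""
    out: dict[str, Any] = {"source_name": module.source_name, "questions": []}
    for q in module.questions:
        d: dict[str, Any] = {
            "id": q.id,
            "text": q.text,
            "position": q.position,
            "options": [
                {k: v for k, v in asdict(o).items() if v is not None}
                for o in q.options
            ],
            "inputs": [
                {k: (v.value if hasattr(v, "value") else v) for k, v in asdict(f).items() if v is not None}
                for f in q.inputs
            ],
        }
        for o in d["options"]:
            o["kind"] = o["kind"].value if hasattr(o["kind"], "value") else o["kind"]
        if q.default_next:
            d["default_next"] = q.default_next
        if q.nr_target:
            d["nr_target"] = q.nr_target
        if q.displayif:
            d["displayif"] = _displayif_to_obj(q.displayif)
        out["questions"].append(d)
    return out
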