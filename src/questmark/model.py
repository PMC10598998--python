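"""Typed in-memory model of a Quest questionnaire module.

A module is an ordered list of question blocks.  Each block carries its
response specification (single-select radio options, multi-select checkbox
options, or typed input fields), plus the skip-logic directives: per-option
arrow jumps, a default-next target, a no-response (#NR) target, and an
optional ``displayif`` guard expression.

The model is deliberately lossless with respect to parsing: option values are
kept as strings, pipe placeholders ``{KEY}`` stay verbatim in question text,
and JSON typing of values is decided only at session finalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Union

END_ID = "END"


class OptionKind(str, Enum):
    RADIO = "radio"
    CHECKBOX = "checkbox"


class InputKind(str, Enum):
    TEXT = "text"
    NUMERIC = "numeric"
    DATE = "date"
    TEL = "tel"
    SSN = "ssn"


@dataclass(frozen=True)
class ResponseOption:
    """One selectable response: ``(value) label`` or ``[value] label``.

    ``jump_target`` holds the question id after an arrow (``-> QID``), if any.
    """

    kind: OptionKind
    value: str
    label: str
    jump_target: str | None = None


@dataclass(frozen=True)
class InputField:
    """A typed free-entry field; min/max only apply to numeric inputs."""

    kind: InputKind
    min: float | None = None
    max: float | None = None


# displayif argument: a question/prefill reference, a literal, or a nested call
@dataclass(frozen=True)
class QuestionRef:
    id: str


DisplayIfArg = Union["DisplayIfExpr", QuestionRef, str, int, float]


@dataclass(frozen=True)
class DisplayIfExpr:
    """A guard expression: ``func(arg, ...)``.

    ``and``/``or`` take >= 2 arguments, comparisons take exactly 2,
    ``exists`` takes 1.  Arity is enforced by the parser.
    """

    func: str  # equals | notEquals | exists | greaterThan | lessThan | and | or
    args: tuple[DisplayIfArg, ...]


@dataclass
class Question:
    """One question block.

    In v1 a block carries options XOR inputs (mixed blocks are rejected at
    parse time); a block with neither is display-only and records no response.
    """

    id: str
    text: str = ""
    options: list[ResponseOption] = field(default_factory=list)
    inputs: list[InputField] = field(default_factory=list)
    default_next: str | None = None
    nr_target: str | None = None
    displayif: DisplayIfExpr | None = None
    position: int = 0
    source_line: int = field(default=0, compare=False)

    @property
    def is_radio(self) -> bool:
        return bool(self.options) and self.options[0].kind is OptionKind.RADIO

    @property
    def is_checkbox(self) -> bool:
        return bool(self.options) and self.options[0].kind is OptionKind.CHECKBOX

    @property
    def is_display_only(self) -> bool:
        return not self.options and not self.inputs


@dataclass
class QuestionnaireModule:
    """Ordered collection of questions with an id index.

    Invariants (enforced by the parser): ids unique, positions contiguous in
    document order, at most one END question.
    """

    questions: list[Question] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict, compare=False)
    source_name: str = field(default="<string>", compare=False)

    def __post_init__(self) -> None:
        if not self.index and self.questions:
            self.reindex()

    def reindex(self) -> None:
        self.index = {q.id: i for i, q in enumerate(self.questions)}

    def __len__(self) -> int:
        return len(self.questions)

    def __contains__(self, qid: str) -> bool:
        return qid in self.index

    def __getitem__(self, qid: str) -> Question:
        return self.questions[self.index[qid]]

    def get(self, qid: str) -> Question | None:
        i = self.index.get(qid)
        return None if i is None else self.questions[i]

    def successor(self, qid: str) -> str | None:
        """Document-order successor id, or None for the last question."""
        i = self.index[qid]
        if i + 1 < len(self.questions):
            return self.questions[i + 1].id
        return None

    @property
    def ids(self) -> list[str]:
        return [q.id for q in self.questions]


@dataclass(frozen=True)
class Diagnostic:
    """A validator finding."""

    severity: str  # "error" | "warning"
    line: int
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity}:{self.code}:line {self.line}: {self.message}"
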