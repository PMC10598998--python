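"""Exception hierarchy for questmark.

Every error raised by the library derives from :class:`QuestError` so callers
can catch one base class at the CLI boundary.
"""

from __future__ import annotations


class QuestError(Exception):
    """Base class for all questmark errors."""


class ParseError(QuestError):
    """Malformed markup.  Carries the 1-based line number of the offence."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line
        self.raw_message = message


class ConfigError(QuestError):
    """Impossible fixture profile or malformed configuration."""


class InvalidModule(QuestError):
    """Module has validation errors and cannot be run or rendered."""


class AnswerValidationError(QuestError):
    """Submitted answer does not conform to the current question's spec."""


class SkipNotAllowed(QuestError):
    """Question is required and declares no #NR routing."""


class StepCapExceeded(QuestError):
    """Session exceeded the configured step cap (cycle guard)."""


class ExpressionError(QuestError):
    """Type error while evaluating a displayif expression."""


class SessionNotFinished(QuestError):
    """finalize() called before the session reached END."""


class VersionMismatch(QuestError):
    """Saved session document does not match the supplied module."""


class RenderError(QuestError):
    """Question violates a structural invariant needed for rendering."""
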