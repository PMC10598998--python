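"""Render parsed modules to standard HTML form markup.

Each response kind maps to its native HTML control: radio options to
``<input type="radio">`` sharing the question id as their ``name``, checkbox
options to ``type="checkbox"``, and input fields to ``text`` / ``number``
(with ``min``/``max`` attributes when declared) / ``date`` / ``tel``, with
SSN rendered as a pattern-constrained text input.  Question text is
HTML-escaped apart from a small inline allowlist (b, i, u, br), and pipe
placeholders are substituted from session context before rendering.

The module renderer emits a static, self-contained HTML5 document with one
``<section>`` per question (identified by the question id) and an optional
external stylesheet link; when no stylesheet is given, no styling is emitted
at all, so the embedding application's appearance wins.  Navigation is not
baked into the document — the session engine is the authoritative navigator.
"""

from __future__ import annotations

import html
import re
from typing import Any

from .engine import resolve_piping
from .errors import InvalidModule, RenderError
from .model import InputKind, OptionKind, Question, QuestionnaireModule

_ALLOWED_TAGS_RE = re.compile(r"&lt;(/?)(b|i|u|br)(\s*/?)&gt;")


def escape_text(text: str) -> str:
    """HTML-escape, letting an inline allowlist (b, i, u, br) through."""
    escaped = html.escape(text, quote=False)
    return _ALLOWED_TAGS_RE.sub(lambda m: f"<{m.group(1)}{m.group(2)}{m.group(3)}>", escaped)


def _attr(value: Any) -> str:
    return html.escape(str(value), quote=True)


def _num_attr(value: float) -> str:
    return f"{value:g}"


def _render_option(qid: str, option, idx: int) -> str:
    input_type = "radio" if option.kind is OptionKind.RADIO else "checkbox"
    elem_id = f"{qid}-{idx}"
    return (
        f'  <label for="{_attr(elem_id)}">'
        f'<input type="{input_type}" id="{_attr(elem_id)}" '
        f'name="{_attr(qid)}" value="{_attr(option.value)}"> '
        f"{escape_text(option.label)}</label>"
    )


def _render_input(qid: str, f, idx: int) -> str:
    elem_id = f"{qid}-{idx}" if idx else qid
    if f.kind is InputKind.NUMERIC:
        attrs = [f'type="number"']
        if f.min is not None:
            attrs.append(f'min="{_num_attr(f.min)}"')
        if f.max is not None:
            attrs.append(f'max="{_num_attr(f.max)}"')
    elif f.kind is InputKind.DATE:
        attrs = ['type="date"']
    elif f.kind is InputKind.TEL:
        attrs = ['type="tel"', 'pattern="[0-9]{3}-[0-9]{3}-[0-9]{4}"']
    elif f.kind is InputKind.SSN:
        attrs = ['type="text"', 'pattern="[0-9]{3}-[0-9]{2}-[0-9]{4}"']
    else:
        attrs = ['type="text"']
    joined = " ".join(attrs)
    return f'  <input {joined} id="{_attr(elem_id)}" name="{_attr(qid)}">'


def render_question(
    question: Question,
    responses: dict[str, Any] | None = None,
    prefill: dict[str, Any] | None = None,
) -> str:
    """Render one question to an HTML fragment (a ``<section>`` element)."""
    if question.options and question.inputs:
        raise RenderError(f"{question.id}: block mixes options and input fields")
    responses = responses or {}
    prefill = prefill or {}
    text = resolve_piping(question.text, responses, prefill)
    lines = [f'<section class="question" id="{_attr(question.id)}">']
    if text:
        lines.append(f"  <p>{escape_text(text)}</p>")
    for i, option in enumerate(question.options):
        lines.append(_render_option(question.id, option, i))
    for i, f in enumerate(question.inputs):
        lines.append(_render_input(question.id, f, i))
    if not question.options and not question.inputs:
        lines.append('  <button type="button" class="continue">Continue</button>')
    lines.append("</section>")
    return "\n".join(lines)


def render_module(
    module: QuestionnaireModule,
    stylesheet_ref: str | None = None,
    responses: dict[str, Any] | None = None,
    prefill: dict[str, Any] | None = None,
) -> str:
    """Render a whole module to a self-contained HTML5 document.

    Raises :class:`InvalidModule` when the module has validation errors.
    """
    from .validator import has_errors, validate_module

    findings = validate_module(module)
    if has_errors(findings):
        raise InvalidModule(
            "module has validation errors: "
            + "; ".join(str(d) for d in findings if d.severity == "error")
        )
    head = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '  <meta charset="utf-8">',
        f"  <title>{escape_text(module.source_name)}</title>",
    ]
    if stylesheet_ref:
        head.append(f'  <link rel="stylesheet" href="{_attr(stylesheet_ref)}">')
    head.append("</head>")
    body = ["<body>", '<form class="questionnaire">']
    for q in module.questions:
        body.append(render_question(q, responses, prefill))
    body.extend(["</form>", "</body>", "</html>"])
    return "\n".join(head + body) + "\n"
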