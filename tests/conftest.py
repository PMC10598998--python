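"""Shared fixtures: the canonical example module and an engine path tracer."""

from __future__ import annotations

import pytest

from questmark import (
    finalize,
    parse_module,
    skip_without_answer,
    start_session,
    submit_answer,
)
from questmark.synthetic_example import (
    SYNTHETIC_EXAMPLE_MARKUP,
    WALKTHROUGH_ANSWERS,
    example_module,
)


@pytest.fixture(scope="session")
def example_markup() -> str:
    return SYNTHETIC_EXAMPLE_MARKUP


@pytest.fixture()
def module():
    return example_module()


@pytest.fixture(scope="session")
def walkthrough_answers() -> dict:
    return dict(WALKTHROUGH_ANSWERS)


def run_with_path(module, answers: dict, config=None):
    """Drive the engine over an answer script, tracing visited question ids.

    Returns (path, payload).  Questions absent from the script are skipped;
    display-only questions are acknowledged without an answer.
    """
    state = start_session(module, config=config)
    path = []
    if state.current_id is not None:
        path.append(state.current_id)
    while not state.finished:
        q = state.current_question
        assert q is not None
        if q.is_display_only:
            submit_answer(state, None)
        elif q.id in answers:
            submit_answer(state, answers[q.id])
        else:
            skip_without_answer(state)
        if state.current_id is not None and (not path or path[-1] != state.current_id):
            path.append(state.current_id)
    return path, finalize(state)


def make_module(text: str):
    return parse_module(text)
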