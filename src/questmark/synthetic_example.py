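"""Synthetic seven-question example module.

This is a synthetic reconstruction of the canonical worked example that ships
with the Quest markup: a short cold/flu symptom module whose skip logic
exercises every navigation rule — a radio arrow that ends the session early,
a multi-select whose chosen options push follow-ups onto the question stack
together with a default-next target, a radio follow-up that either inserts an
extra question or pops the stack, and a bounds-checked numeric input.

The reference walkthrough answers QUESTION_1 with (2), selects 13 (runny
nose) and 15 (fever) at QUESTION_2, answers No at DECON1 and 98 at TEMP,
producing the payload::

    {"DECON1": 0, "QUESTION_1": 2, "QUESTION_2": [13, 15], "TEMP": 98}

DECON2 and SORE_THROAT are reachable only on other paths and are absent from
that payload.
"""

from __future__ import annotations

from .model import QuestionnaireModule
from .parser import parse_module

SYNTHETIC_EXAMPLE_MARKUP = """\
[QUESTION_1] Have you had a cold or flu-like illness in the last 30 days?
(1) No -> END
(2) Yes

[QUESTION_2] Which symptoms did you have? Select all that apply. < -> END>
[13] runny nose -> DECON1
[14] sore throat -> SORE_THROAT
[15] fever -> TEMP

[DECON1] Did you see a doctor about your illness?
(1) Yes -> DECON2
(0) No

[DECON2] What did the doctor recommend?
|__|

[SORE_THROAT] How many days did your sore throat last?
|__|__| min=0 max=30

[TEMP] What was your highest temperature, in degrees Fahrenheit?
|__|__| min=90 max=120

[END] Thank you for completing this module.
"""

#: Answers reproducing the reference walkthrough, keyed by question id.
WALKTHROUGH_ANSWERS: dict[str, object] = {
    "QUESTION_1": "2",
    "QUESTION_2": ["13", "15"],
    "DECON1": "0",
    "TEMP": 98,
}


def example_module() -> QuestionnaireModule:
    """Parse and return the synthetic example module."""
    return parse_module(SYNTHETIC_EXAMPLE_MARKUP, source_name="synthetic_example")
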