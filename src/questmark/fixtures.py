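"""Seeded random questionnaire generator and scripted-answer simulation.

The generator emits valid Quest markup by construction: every arrow,
default-next and ``#NR`` target points strictly forward in document order, so
the jump graph is acyclic and END is always reachable; option values are
numeric strings, which can never collide with the question-id grammar.  It
powers the property-test surface (round-trip, termination, oracle
equivalence) and the ``quest fixtures`` CLI subcommand.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .engine import EngineConfig, finalize, skip_without_answer, start_session, submit_answer
from .errors import ConfigError
from .model import InputKind, OptionKind, QuestionnaireModule

_WORDS = (
    "often rarely never daily weekly cough fever chills fatigue headache "
    "mild moderate severe past month year doctor clinic symptom onset"
).split()

POLICIES = ("first_option", "random", "skip_all")


@dataclass(frozen=True)
class FixtureProfile:
    """Mix of question kinds and logic density for generated modules.

    Probabilities of radio/checkbox/input/display-only questions are
    normalized; ``arrow_prob`` applies per option, the rest per question.
    """

    p_radio: float = 0.40
    p_checkbox: float = 0.25
    p_input: float = 0.25
    p_display: float = 0.10
    min_options: int = 2
    max_options: int = 4
    arrow_prob: float = 0.4
    default_next_prob: float = 0.5
    nr_prob: float = 0.3
    displayif_prob: float = 0.15

    def validate(self) -> None:
        weights = (self.p_radio, self.p_checkbox, self.p_input, self.p_display)
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigError(f"question-kind weights must be >=0 and not all zero: {weights}")
        if not 1 <= self.min_options <= self.max_options:
            raise ConfigError(
                f"need 1 <= min_options <= max_options, got {self.min_options}..{self.max_options}"
            )
        for name in ("arrow_prob", "default_next_prob", "nr_prob", "displayif_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")


def generate_random_module(
    n_questions: int,
    profile: FixtureProfile | None = None,
    seed: int = 0,
) -> str:
    """Emit markup with *n_questions* blocks plus ``[END]``.

    Deterministic per seed; the output always parses and validates with zero
    errors, and every session on it terminates (arrows only point forward).
    """
    if n_questions < 1:
        raise ConfigError(f"n_questions must be >= 1, got {n_questions}")
    profile = profile or FixtureProfile()
    profile.validate()
    rng = random.Random(seed)
    ids = [f"Q{i + 1}" for i in range(n_questions)] + ["END"]
    weights = (profile.p_radio, profile.p_checkbox, profile.p_input, profile.p_display)

    def words(k: int) -> str:
        return " ".join(rng.choice(_WORDS) for _ in range(k))

    def forward_target(i: int) -> str:
        return rng.choice(ids[i + 1:])

    blocks: list[str] = []
    radio_values: dict[str, list[str]] = {}  # earlier radio questions, for displayif
    for i, qid in enumerate(ids[:-1]):
        kind = rng.choices(("radio", "checkbox", "input", "display"), weights=weights)[0]
        lines = [f"[{qid}] {words(4).capitalize()}?"]
        if radio_values and rng.random() < profile.displayif_prob:
            ref = rng.choice(sorted(radio_values))
            value = rng.choice(radio_values[ref])
            lines.append(f"<displayif equals({ref}, {value})>")
        if kind in ("radio", "checkbox") and rng.random() < profile.nr_prob:
            lines.append(f"<#NR -> {forward_target(i)}>")
        if kind == "checkbox" and rng.random() < profile.default_next_prob:
            lines.append(f"< -> {forward_target(i)}>")
        if kind in ("radio", "checkbox"):
            n_opts = rng.randint(profile.min_options, profile.max_options)
            values = [str(v) for v in rng.sample(range(100), n_opts)]
            brackets = "()" if kind == "radio" else "[]"
            for v in values:
                arrow = f" -> {forward_target(i)}" if rng.random() < profile.arrow_prob else ""
                lines.append(f"{brackets[0]}{v}{brackets[1]} {words(2)}{arrow}")
            if kind == "radio":
                radio_values[qid] = values
        elif kind == "input":
            which = rng.choice(("text", "numeric", "date"))
            if which == "numeric":
                lo = rng.randint(0, 50)
                hi = lo + rng.randint(1, 50)
                lines.append(f"|__|__| min={lo} max={hi}")
            elif which == "date":
                lines.append("|date|")
            else:
                lines.append("|__|")
        blocks.append("\n".join(lines))
    blocks.append("[END] " + words(3).capitalize() + ".")
    return "\n\n".join(blocks) + "\n"


def _policy_answer(question, policy: str, rng: random.Random):
    if question.is_radio:
        pool = [o.value for o in question.options]
        return pool[0] if policy == "first_option" else rng.choice(pool)
    if question.is_checkbox:
        pool = [o.value for o in question.options]
        if policy == "first_option":
            return [pool[0]]
        k = rng.randint(1, len(pool))
        return sorted(rng.sample(pool, k), key=pool.index)
    if question.inputs:
        f = question.inputs[0]
        if f.kind is InputKind.NUMERIC:
            lo = int(f.min) if f.min is not None else 0
            hi = int(f.max) if f.max is not None else lo + 100
            return lo if policy == "first_option" else rng.randint(lo, hi)
        if f.kind is InputKind.DATE:
            return "2024-01-15"
        if f.kind is InputKind.TEL:
            return "301-555-0134"
        if f.kind is InputKind.SSN:
            return "987-65-4321"
        return "free text"
    return None


def simulate_answer_script(
    module: QuestionnaireModule,
    policy: str = "first_option",
    seed: int = 0,
) -> dict:
    """Produce an answer script (question-id -> answer) under *policy*.

    ``skip_all`` yields an empty script; the other policies replay a session,
    answering each question encountered, so the script is consistent with the
    path the engine actually takes.  Deterministic per seed.
    """
    if policy not in POLICIES:
        raise ConfigError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy == "skip_all":
        return {}
    rng = random.Random(seed)
    script: dict = {}
    state = start_session(module, validate=False)
    while not state.finished:
        q = state.current_question
        assert q is not None
        answer = _policy_answer(q, policy, rng)
        if answer is None:
            submit_answer(state, None)
        else:
            script[q.id] = answer
            submit_answer(state, answer)
    finalize(state)
    return script


def run_policy(
    module: QuestionnaireModule,
    policy: str,
    seed: int = 0,
    config: EngineConfig | None = None,
) -> dict:
    """Run a full session under *policy* and return the finalized payload."""
    from .engine import run_script

    script = simulate_answer_script(module, policy, seed)
    return run_script(module, script, config=config)
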