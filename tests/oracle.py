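"""Independent brute-force session walker used as a test oracle.

Re-implements the stack navigation rules directly from their narrative
description, sharing no code with questmark.engine: answering a question
first remembers the default-next target (always), then either follows a
selected radio arrow, or queues the chosen checkbox arrows so they are
visited in the order their options are written, and otherwise takes the most
recently remembered pending question, falling back to whatever block comes
next in the file.  Used to cross-check (path, payload) pairs by exhaustive
enumeration on tiny modules.

Restricted to modules without displayif guards (asserted), so the oracle
stays trivially auditable.
"""

from __future__ import annotations

import re

_PLAIN_INT = re.compile(r"-?(0|[1-9][0-9]*)")


def _typed(v):
    if isinstance(v, str) and _PLAIN_INT.fullmatch(v):
        return int(v)
    return v


def walk(module, answers: dict, max_steps: int = 10_000):
    """Replay *answers* over *module*; return (visited id list, payload).

    *answers* maps question id -> raw answer (option value string, list of
    value strings, or input value); ids absent from the mapping are skipped.
    """
    order = [q.id for q in module.questions]
    assert all(q.displayif is None for q in module.questions), "oracle: no displayif support"
    byid = {q.id: q for q in module.questions}
    pending: list[str] = []
    path: list[str] = []
    payload: dict = {}
    cur = order[0] if order else None

    for _ in range(max_steps):
        if cur is None:
            return path, payload
        path.append(cur)
        q = byid[cur]
        answer = answers.get(cur)
        radio = bool(q.options) and q.options[0].kind.value == "radio"

        # record the response
        if answer is not None:
            if radio:
                payload[cur] = _typed(str(answer))
            elif q.options:
                picked = [str(a) for a in (answer if isinstance(answer, list) else [answer])]
                payload[cur] = [_typed(o.value) for o in q.options if o.value in picked]
            else:
                payload[cur] = _typed(answer) if isinstance(answer, str) else answer

        if cur == "END":
            return path, payload

        # the default-next target is always remembered
        if q.default_next is not None:
            pending.append(q.default_next)

        # direct transfers: no-response routing, or a selected radio arrow
        if answer is None and (q.options or q.inputs) and q.nr_target is not None:
            cur = q.nr_target
            continue
        if answer is not None and radio:
            chosen = next(o for o in q.options if o.value == str(answer))
            if chosen.jump_target is not None:
                cur = chosen.jump_target
                continue
        if answer is not None and q.options and not radio:
            picked = [str(a) for a in (answer if isinstance(answer, list) else [answer])]
            for o in reversed(q.options):
                if o.value in picked and o.jump_target is not None:
                    pending.append(o.jump_target)

        # otherwise: most recent pending question, else document order
        if pending:
            cur = pending.pop()
        else:
            i = order.index(cur)
            cur = order[i + 1] if i + 1 < len(order) else None
    raise AssertionError("oracle walker did not terminate")
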