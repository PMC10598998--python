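"""Static checks on parsed modules.

The validator never raises on parser output: it returns a list of
:class:`~questmark.model.Diagnostic` findings.  Anything that could crash a
session (dangling jump targets, duplicate option values, inverted numeric
bounds, a missing END question, displayif references to unknown ids) is an
error; anything that merely risks dead content or non-termination
(unreachable questions, directed cycles) is a warning.

Reachability and cycle analysis run on a jump graph that over-approximates
dynamic navigation: it includes the document-order fallthrough edge from each
non-END question to its successor in addition to every declared arrow,
default-next and ``#NR`` edge, so any question an actual session can visit is
reachable in the graph.
"""

from __future__ import annotations

import networkx as nx

from .model import END_ID, Diagnostic, DisplayIfExpr, InputKind, QuestionnaireModule, QuestionRef


def build_jump_graph(module: QuestionnaireModule) -> nx.DiGraph:
    """Directed graph over question ids.

    Edge kinds (edge attribute ``kind``): ``arrow`` (per-option jump),
    ``default`` (default-next), ``nr`` (no-response target), ``fallthrough``
    (document-order successor).  Dangling targets appear as nodes so that
    reachability checks do not crash; validate_module flags them.
    """
    g = nx.DiGraph()
    g.add_nodes_from(module.ids)
    for q in module.questions:
        for o in q.options:
            if o.jump_target is not None:
                g.add_edge(q.id, o.jump_target, kind="arrow")
        if q.default_next is not None:
            g.add_edge(q.id, q.default_next, kind="default")
        if q.nr_target is not None:
            g.add_edge(q.id, q.nr_target, kind="nr")
        succ = module.successor(q.id)
        if q.id != END_ID and succ is not None and not g.has_edge(q.id, succ):
            g.add_edge(q.id, succ, kind="fallthrough")
    return g


def _displayif_refs(expr: DisplayIfExpr) -> set[str]:
    refs: set[str] = set()
    for arg in expr.args:
        if isinstance(arg, QuestionRef):
            refs.add(arg.id)
        elif isinstance(arg, DisplayIfExpr):
            refs |= _displayif_refs(arg)
    return refs


def validate_module(module: QuestionnaireModule) -> list[Diagnostic]:
    """Run all static checks; returns diagnostics, never raises."""
    findings: list[Diagnostic] = []

    def error(line: int, code: str, message: str) -> None:
        findings.append(Diagnostic("error", line, code, message))

    def warning(line: int, code: str, message: str) -> None:
        findings.append(Diagnostic("warning", line, code, message))

    defined = set(module.index)

    for q in module.questions:
        for o in q.options:
            if o.jump_target is not None and o.jump_target not in defined:
                error(q.source_line, "dangling-target",
                      f"{q.id}: arrow target {o.jump_target!r} is not defined")
        if q.default_next is not None and q.default_next not in defined:
            error(q.source_line, "dangling-target",
                  f"{q.id}: default-next target {q.default_next!r} is not defined")
        if q.nr_target is not None and q.nr_target not in defined:
            error(q.source_line, "dangling-target",
                  f"{q.id}: #NR target {q.nr_target!r} is not defined")

        values = [o.value for o in q.options]
        for v in sorted({v for v in values if values.count(v) > 1}):
            error(q.source_line, "duplicate-value",
                  f"{q.id}: option value {v!r} declared more than once")

        for f in q.inputs:
            if f.kind is InputKind.NUMERIC and f.min is not None and f.max is not None:
                if f.min > f.max:
                    error(q.source_line, "inverted-bounds",
                          f"{q.id}: numeric min {f.min:g} exceeds max {f.max:g}")

        if q.displayif is not None:
            for ref in sorted(_displayif_refs(q.displayif) - defined):
                warning(q.source_line, "displayif-unknown-ref",
                        f"{q.id}: displayif references {ref!r}, which is not a "
                        "question id (treated as prefill)")

    if END_ID not in defined:
        error(0, "no-end", "module has no END question")

    if module.questions:
        g = build_jump_graph(module)
        # restrict to defined nodes: dangling targets were flagged above
        g = g.subgraph(defined).copy()
        first = module.questions[0].id
        reachable = {first} | nx.descendants(g, first)
        for q in module.questions:
            if q.id not in reachable:
                warning(q.source_line, "unreachable",
                        f"{q.id} is unreachable from {first}")
        if END_ID in defined and END_ID not in reachable:
            warning(module[END_ID].source_line, "end-unreachable",
                    f"END is unreachable from {first}")
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = []
        if cycle:
            path = " -> ".join([e[0] for e in cycle] + [cycle[-1][1]])
            warning(module[cycle[0][0]].source_line, "cycle",
                    f"directed cycle among jump edges: {path} (possible non-termination)")

    return findings


def has_errors(findings: list[Diagnostic]) -> bool:
    return any(d.severity == "error" for d in findings)
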