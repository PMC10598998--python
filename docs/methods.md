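# Methods

## The model

A Quest module is an ordered sequence of question blocks. Each block has a
unique id (capital first letter, then capitals, digits, `_` or `#`; the
final block is `END`), free question text, and one response specification:
single-select options `(value) label`, multi-select options
`[value] label`, or typed input fields. Option values may not themselves be
valid question ids — that restriction is what makes the line grammar
decidable: a line whose first token is `[X]` is a block header exactly when
`X` passes the id grammar, and a checkbox option otherwise.

Skip logic is declarative. A per-option arrow `-> QID` routes the session
when that option is selected; `< -> QID>` declares a default-next target;
`<#NR -> QID>` routes a participant who answers nothing; and
`<displayif f(...)>` guards a question on earlier answers.

## Session semantics

The interpreter keeps a LIFO stack of pending question ids.

1. Answering any question first pushes its default-next target, when one is
   declared. This holds for every response kind, including a single-select
   whose chosen option carries an arrow: the arrow transfers control
   directly, and the default-next target remains on the stack to be visited
   later. That combination is the only reading consistent with both
   "the default next question is always added to the stack" and direct
   radio transfer, and it reproduces the canonical walkthrough exactly.
2. A selected single-select arrow transfers directly. Selected multi-select
   arrows are pushed in **reverse declaration order**, so popping visits
   follow-ups in the order their options are written in the block.
3. Otherwise the next question is popped from the stack; with an empty
   stack it is the next block in document order.
4. A question whose `displayif` is false at arrival is skipped
   transparently — nothing is recorded, and navigation continues by rule 3
   from the skipped block. The same rule chooses the session's first
   question.
5. `END` terminates the session on arrival when it is display-only;
   an `END` with input fields terminates once answered or skipped.

Every transition counts against a step cap (default 10× the question
count, configurable) so cyclic markup surfaces as `StepCapExceeded`
instead of a hang. Re-answering after back-navigation is out of scope:
responses are write-once per session and replayed scripts are keyed by
question id.

### Answer constraints

Single-select answers must be one of the declared option values;
multi-select answers must be subsets (normalized to declaration order);
numeric inputs are checked against the closed interval `[min, max]` when
bounds are declared; dates must be ISO `YYYY-MM-DD`; telephone numbers
`ddd-ddd-dddd`; SSNs `ddd-dd-dddd`.

### The payload contract

On completion the responses serialize to a flat JSON object handed to any
registered completion hook (the library analogue of a browser callback):
scalars for single-select and input answers, lists for multi-select. A
recorded string is emitted as a number iff it matches an optional minus
sign followed by digits without leading zeros (plus plain `0`); this
reproduces unquoted numeric codes without corrupting codes like `"007"`.
Canonical serialization is UTF-8 with sorted keys.

## Dialect decisions

Several surface details are fixed here because the markup's informal
description leaves them open; each is isolated in one function so an
alternative convention can replace it:

* **Numeric bounds** — `|__|__| min=<n> max=<n>` after the pipe token
  (either annotation may be omitted; `min ≤ max` enforced).
* **Piping** — `{KEY}` in question text substitutes the response for
  `KEY`, else the prefill value, else stays verbatim.
* **displayif grammar** — `func(arg, ...)` with the function vocabulary
  `equals`, `notEquals`, `exists`, `greaterThan`, `lessThan`, `and`, `or`;
  arguments are question references, numeric or quoted string literals, or
  nested calls. Comparisons take exactly two arguments, `exists` one,
  `and`/`or` at least two. A reference to an unanswered question makes a
  comparison false rather than raising (participants legitimately skip
  questions), while a type mismatch in an order comparison is an
  `ExpressionError`. Numeric coercion applies when both sides are numeric;
  a multi-select answer compares by membership.
* **Directive whitespace** — `<->ID>`, `< -> ID >` and `<#NR->ID>` are all
  accepted; directives may appear anywhere in a block, including the header
  line.
* **Mixed blocks** — a block declaring both options and input fields is a
  parse error; submit semantics for such blocks are undefined here.

## Validation policy

Anything that can crash a session is an error: dangling arrow/default/#NR
targets, duplicate option values within a question, inverted numeric
bounds, a missing `END`. Anything that merely risks dead content is a
warning: unreachable questions, directed cycles, `displayif` references
that match no question id (legal when the key arrives via prefill).
Reachability and cycles are computed on a jump graph (networkx) that
includes document-order fallthrough edges from every non-`END` block, so
static reachability over-approximates dynamic reachability — no question a
session can visit is ever reported unreachable. Termination in the
presence of `displayif` is not decided statically; the step cap handles it
at run time.

## The fixture generator

`generate_random_module` emulates the module shapes the format targets:
mixed single-select / multi-select / input / display-only blocks, numeric
bounds, default-next and no-response routing, and `displayif` guards
referencing earlier single-select questions. Its guarantees are structural,
by construction: every emitted target points strictly forward in document
order, so the jump graph is acyclic and `END` is always reachable, and
option values are numeric strings, which can never collide with the id
grammar. Defaults (40% radio, 25% checkbox, 25% input, 10% display-only;
2–4 options; arrow probability 0.4; default-next 0.5 on multi-selects;
no-response 0.3; displayif 0.15) were chosen once to resemble a short
epidemiologic symptom module with moderate logic density.

What generated fixtures deliberately do **not** exercise: backward arrows
(real modules may loop; here cycles appear only in hand-written test
modules), the expert grammar (loops, grids), rich text beyond the inline
allowlist, and non-ASCII ids. Passing the property suites therefore shows
the interpreter is correct for acyclic forward-routed modules and guarded
against cycles, not that every wiki-level construct is supported.

## Test design

Unit tests pin the line grammar, directive forms and error lines.
Property suites check: parse→serialize→parse is a fixed point on 200
seeded modules; sessions terminate under `first_option` / `random` /
`skip_all` answer policies on all fixtures; save/load at every step never
changes the final payload; rendered documents parse as HTML and contain
exactly the model's option values. The engine is additionally compared,
by exhaustive enumeration of all answer combinations (including skips), to
an independent brute-force walker written directly from the narrative
navigation rules (`tests/oracle.py`), on hand-written and generated
modules of ≤5 questions and ≤3 options without `displayif`. Problem sizes
(200 seeds, 6-question fixtures, ≤5-question enumeration) keep the full
suite under a minute while covering every navigation rule.

## Rendering choices

Output is a static HTML5 document, one `<section id="QID">` per question;
navigation is left to the embedding application because the session engine
is the authoritative navigator. Question text is HTML-escaped except for
an inline allowlist (`b`, `i`, `u`, `br`). SSN maps to a
pattern-constrained text input since HTML has no native SSN type. When no
stylesheet reference is given the document carries no styling at all, so
the host application's appearance wins.

## Known limitations

* The expert-level grammar (loops, responsive grids) is out of scope; the
  step cap is the only defence against repetition constructs.
* One input field per block is the supported answering surface; multiple
  fields in one block validate element-wise against a list answer but have
  no per-field ids in the payload.
* The `displayif` vocabulary is a minimal core of seven functions.
* Skipped questions leave no marker in the payload (answered keys only).
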