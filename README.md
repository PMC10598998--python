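# questmark

A Python toolkit for the **Quest questionnaire markup language**: a
plain-text format for epidemiologic data-collection instruments in which
question blocks carry an id in square brackets, single-select `(value)` or
multi-select `[value]` response options, typed input fields (`|__|`,
`|__|__|`, `|date|`, `|tel|`, `|SSN|`), and skip logic expressed as
per-option arrows (`response -> QID`), a default-next target (`< -> QID>`),
no-response routing (`<#NR -> QID>`) and `displayif` guard expressions.

Study teams write questionnaires as readable text; `questmark` turns that
text into data collection:

* **parser / serializer** — markup ⇄ a typed `QuestionnaireModule`, with a
  canonical round-tripping serializer and a JSON parse-tree export;
* **validator** — static checks (dangling jump targets, duplicate option
  values, inverted numeric bounds, missing `END`, unreachable questions,
  cycles) over a jump graph;
* **session engine** — executes participant sessions under the stack
  semantics (below), enforces answer constraints, supports prefilled data,
  text piping (`{AGE}`), save/resume, and emits the completion payload to a
  registered callback;
* **HTML renderer** — standard form elements (`radio`, `checkbox`,
  `number` with `min`/`max`, `date`, `tel`, pattern-constrained SSN), with
  an optional external stylesheet and no styling otherwise;
* **fixtures** — a seeded random-module generator and answer-script
  simulator powering the property-test suite;
* **`quest` CLI** — `validate`, `render`, `run`, `ast`, `fixtures`.

## Navigation semantics

Sessions maintain a LIFO stack of pending question ids. Answering a
question pushes its declared default-next target; a selected single-select
arrow transfers directly; selected multi-select arrows are pushed in
reverse declaration order so follow-ups are visited in the order their
options are written. With nothing to jump to, the next question is popped
from the stack, and when the stack is empty it is the next block in
document order. A question whose `displayif` guard is false at arrival is
skipped transparently and recorded nowhere. On completion, answers
serialize to a flat JSON object — scalars for single-select and input
answers, declaration-ordered lists for multi-select — with digit-only
values typed as numbers (`"98"` → `98`, but `"007"` stays a string).

## Worked example

The bundled example module (`questmark.synthetic_example`, a synthetic
reconstruction of the canonical seven-question cold/flu module) starts at
`QUESTION_1`; choosing option `(1)` would jump straight to `END`, so the
walkthrough picks `(2)`, selects symptoms `13` and `15` at the multi-select
`QUESTION_2` (pushing `DECON1`, `TEMP` and the default-next `END` onto the
stack), answers No at `DECON1` (so `DECON2` is never inserted) and records
a temperature of 98, which `TEMP` bounds-checks against [90, 120]:

```python
from questmark import parse_module, run_script, payload_json
from questmark.synthetic_example import SYNTHETIC_EXAMPLE_MARKUP

module = parse_module(SYNTHETIC_EXAMPLE_MARKUP)
payload = run_script(module, {
    "QUESTION_1": "2",
    "QUESTION_2": ["13", "15"],
    "DECON1": "0",
    "TEMP": 98,
})
print(payload_json(payload))
```

prints

```
{"DECON1":0,"QUESTION_1":2,"QUESTION_2":[13,15],"TEMP":98}
```

i.e. the participant's personalized path visited four of the seven
questions, the two selected symptom codes are kept in option order, and all
values are numerically typed. The same session runs from the shell:

```sh
quest run example.quest --answers answers.json -o responses.json
quest validate example.quest --strict
quest render example.quest -o example.html --style Style1.css
```

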