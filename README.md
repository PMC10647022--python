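# synthroles

A toolkit for **semantic-role annotation of organic synthesis procedures**:
verb rolesets, a six-entity/four-relation annotation schema, brat standoff
I/O, a deterministic rule-based extraction pipeline, NER/RE evaluation with
exact and relaxed span matching, action-sequence construction, and a seeded
synthetic corpus generator.

## Who this is for

Reproducing a reaction requires more than the bag of chemicals: *"A is added
to B"* and *"B is added to A"* are different procedures. Procedure-extraction
corpora therefore need the *semantic role* each entity plays with respect to
each action verb. This package implements that representation end to end for
people building or consuming such corpora: annotation tooling and validation
for corpus builders, scoring and format exports for model developers, and a
text-aligned action-sequence view for chemists who need to verify extracted
procedures against the original wording.

## The representation

Each action verb carries a **roleset** — a PropBank-style verb sense with
described, numbered argument slots, capped at ARG2 and always sense `.01`
(one roleset per verb). For example:

```
add.01    ARG1: thing being added    ARG2: thing being added to
mix.01    ARG1: ingredient
contain.01  ARG0: container  ARG1: thing contained
```

Annotation uses six span labels — `REACTION_STEP` (the action verb, synthesis
part only), `ENTITY` (substances, gases, vessels), and the parameters `TIME`,
`TEMPERATURE`, `TEMP_TARGET`, `MODIFIER` — and four relation labels from a
`REACTION_STEP` to an argument: `ARG1`/`ARG2` (to an `ENTITY`), `ARGM` (to a
parameter), and `ARG0`, reserved for the container of *contain* (agents are
otherwise always the experimenter). Two corpus policies are enforced in code:
repeated parameter values are annotated only at first mention, and an
entity's amount or coreference label — `“12-aminododecanolactam (1)
(9.00 g, 45.6 mmol, 1.00 equiv)”` — stays inside one span.

Rolesets carry an origin type: **A** (taken from PropBank), **B** (argument
definitions changed), **C** (new roleset, verb in PropBank), **D** (new
roleset, new verb). The packaged registry
(`src/synthroles/data/rolesets.tsv`) is a plain TSV that chemists can extend
without touching code.

Evaluation is precision/recall/F over spans (exact, or *relaxed*: any
character overlap with the correct label, one-to-one) and over relations
(head, tail and label must all match).

## Worked example

```python
from synthroles import run_pipeline, build_sequence, render_text

text = ("The flask was charged with 12-aminododecanolactam (1) "
        "(9.00 g, 45.6 mmol, 1.00 equiv). Anhydrous CH2Cl2 (150 mL) was added "
        "dropwise to the flask (Note 11). The mixture was stirred at "
        "room temperature (23 °C) for 12 h.")
doc = run_pipeline(text)          # NER + RE with the rule baseline
print(render_text(build_sequence(doc)))
```

prints

```
1. Charge The flask → 12-aminododecanolactam (1) (9.00 g, 45.6 mmol, 1.00 equiv)
2. Add Anhydrous CH2Cl2 (150 mL) → the flask (MODIFIER: dropwise)
3. Stir The mixture (TEMPERATURE: room temperature (23 °C), TIME: 12 h)
```

One numbered step per action verb, in text order: the `(Note 11)`
cross-reference was stripped before tagging, `charged` resolved to
`charge.01` with the vessel as ARG1 and the material as ARG2, the dosing
mode and the time/temperature parameters attached as ARGM, and every
argument string is the exact slice of the original text (each step also
records the verb's character span), so the output can be checked against
the source line by line.

The same workflows are available from the shell:

```bash
synthroles generate --seed 7 --n 20 corpus/      # synthetic gold corpus
synthroles extract corpus/all pred/              # rule pipeline
synthroles eval-ner --criterion relaxed corpus/all pred/
synthroles eval-re --entities predicted corpus/all pred/
synthroles sequence corpus/all
```

## Layout

| module | contents |
| --- | --- |
| `synthroles.schema` | domain types, structural + roleset validation |
| `synthroles.rolesets` | registry TSV loading, lemmatization, slot queries |
| `synthroles.brat` | standoff parse/serialize, Note/Figure stripping, sentence split, tokenizer, IOB2 / marked-pair exports |
| `synthroles.pipeline` | tagger & classifier contracts, rule/lexicon baseline, first-mention filter |
| `synthroles.evaluation` | exact/relaxed NER scoring, RE scoring, per-verb recall, count recovery |
| `synthroles.sequencer` | text-aligned action sequences, text/JSON rendering |
| `synthroles.synthetic` | seeded corpus generator, splits, statistics |
| `synthroles.cli` | `synthroles` command-line interface |

See `docs/methods.md` for the design notes: what the rule baseline covers,
what the synthetic corpus does and does not emulate, and the numerical
conventions used in scoring.
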