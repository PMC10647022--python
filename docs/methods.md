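# Methods

## The annotation model

A procedure document is a raw text plus two annotation layers. Spans carry
one of six labels: `REACTION_STEP` — an action that transforms reactants
toward the product (workup operations and instrument preparation are
excluded by policy); `ENTITY` — substances, gases, vessels and other
apparatus standing in a semantic relation to an action; and four parameter
labels: `TIME` (durations, ranges such as `14–15 h`, and word expressions
such as `overnight`), `TEMPERATURE` (values, ranges such as
`between 0 °C and 5 °C`, word expressions such as `room temperature`, and
indirect expressions such as `ice/water`), `TEMP_TARGET` (where a
temperature is maintained — `internal temperature`, `bath temperature`), and
`MODIFIER` (atmosphere, dosing mode, parallel actions such as `with
stirring`). Relations link an action to its arguments: `ARG1`/`ARG2` to
entities with roleset-specific meanings, `ARGM` to any parameter, and `ARG0`
only for the container of *contain* — every other action's agent is the
experimenter and is not annotated.

Two policies are load-bearing downstream. **First mention**: a repeated
parameter value is annotated only at its first occurrence, because repeats
confuse the conversion to an action sequence; the pipeline applies the same
filter to its own predictions. **One span**: coreference labels and amounts
belong to the entity span they follow.

Each verb lemma maps to exactly one roleset, sense-suffixed `.01`, with
numbered slots capped at ARG2 (slots are renumbered downward so that rare
high-numbered labels never occur). Rolesets record an origin type: A —
PropBank as-is or lightly reworded; B — argument definitions changed (e.g.
*mix*, whose two syntactic "ingredient" slots collapse into a single ARG1,
the distinction being chemically irrelevant); C — new roleset for a verb
PropBank knows; D — new roleset for a verb PropBank lacks.

The packaged registry holds the 21 rolesets recoverable from published
sources (the full 48-roleset inventory is not distributed); it is a data
file, not a constant, and extending it requires no code change. Slot
descriptions for verbs whose rolesets are not spelled out publicly follow
one convention: the passive surface subject is ARG1 (so `the flask was
charged with X` has the vessel as ARG1 and X as ARG2), keeping the rule
classifier's syntax→role mapping uniform across verbs.

## Lemmatization

Action surfaces are resolved to lemmas by (1) a packaged surface→lemma
dictionary covering noun forms (`addition → add`) and irregular inflections
(`held → hold`), then (2) suffix stripping (`-ing`, `-ed`, `-es`, `-s`) with
candidate bases (bare, restored final *-e*, undoubled final consonant)
confirmed against the known lemma set. Unknown tokens return unchanged
(lowercased), which makes the function idempotent and lets downstream code
flag unseen verbs instead of inventing rolesets. This is a deliberately
small, deterministic component: the inflection inventory of synthesis verbs
is tiny and closed, and determinism matters more here than linguistic
coverage.

## Text processing

All offsets are 0-based half-open character offsets over the raw text (brat
convention), newlines preserved.

* **Cross-reference stripping.** Parenthesized `(Note n)` / `(Figure n)`
  references (including `(Notes 3 and 5)`, `(Notes 3–5)`), an artifact of
  the source journal, are removed together with one preceding space. An
  offset map records, for every cleaned-text position, its original
  position, so predictions made on cleaned text are reported in original
  coordinates; a mapped span that straddles a removed region re-includes it
  (does not occur for references inserted between annotations). All other
  parentheses — amounts, coreference labels, inline temperatures — are
  untouched.
* **Sentence splitting** is rule-based with a fixed abbreviation list
  (`equiv`, `aq`, `fig`, …): a `.`/`!`/`?` ends a sentence only before
  whitespace followed by an uppercase letter or digit. Pinned rather than
  delegated to an external splitter so that exports are bit-stable.
* **Tokenization** is one documented regex
  (`[\w°]+(?:\.\d+)?(?:[-–/][\w°]+(?:\.\d+)?)*|\S`): decimal numbers,
  ranges (`14–15`), `°C`, and hyphen/slash-joined tokens (`ice/water`,
  `12-aminododecanolactam`) stay whole; any other symbol is its own token.
  The regex is part of the public contract because IOB2 exports must be
  reproducible byte for byte.

## The extraction pipeline

Extraction runs as NER → RE. NER uses three independent per-sentence tracks
(actions / entities / parameters) because labels from different tracks may
legitimately overlap while spans within one track never do; the pipeline
takes the union of the tracks. RE then classifies every intra-sentence
(action, other-mention) pair — candidate pairs never cross sentences — into
a relation label or NONE, using marker notation (`[E1]…[/E1]`,
`[E2]…[/E2]`).

Both stages are *contracts* (token sequence → IOB2 tags; marked instance →
label), so a learned model can be plugged in unchanged. The shipped
reference implementation is deliberately rule- and lexicon-based:

* the **action tagger** tags tokens whose lemma resolves in the registry,
  in verb contexts only (sentence-initial imperative, after
  *was/were/is/are/to/then/and*, third-person present, or a dictionary noun
  form followed by *of*);
* the **entity tagger** is lexicon-driven (longest phrase match) and absorbs
  following parenthesized amount/coreference groups into the span;
* the **parameter tagger** combines numeric patterns (value + unit,
  signed temperatures, `between X °C and Y °C` ranges) with word lexicons
  for temperature words, temperature targets and modifiers;
* the **relation classifier** implements the schema's syntax→role mapping:
  parameters attach (ARGM) to the nearest action; a preceding subject with
  no intervening action or entity is ARG1 (ARG0 for *contain*); the object
  of *to/into/in/onto/with* after the verb is ARG2 when the roleset defines
  that slot and otherwise folds into ARG1; a bare direct object is ARG1.

Two known limitations are reproduced on purpose rather than patched around.
The pipeline makes no attempt to detect the synthesis/workup boundary, so a
sentence containing workup verbs (e.g. a workup *wash*) yields
REACTION_STEP false positives — the characteristic precision failure of
systems trained on synthesis-only annotation. And when a prediction assigns
a relation label the head's roleset does not define (ARG2 on `mix.01`),
validation and sequencing flag it as a warning instead of an error: such
predictions are correctable by consulting the roleset's slots, so the data
is kept.

## Evaluation

Precision, recall and F are computed from integer TP/FP/FN with the 0/0 → 0
convention. Exact span scoring requires identical span sets and labels.
Relaxed scoring counts any character overlap with the correct label, under
one-to-one assignment: predictions in start-offset order claim the
earliest-ending unmatched overlapping gold mention. For span sets that are
disjoint within each side — which annotation policy and IOB2 decoding both
guarantee per label — this greedy assignment attains the maximum bipartite
matching (property-tested against brute force); a many-to-one variant
exists behind a flag. Relation scoring requires the head mention, tail
mention and relation label to all match; endpoint identification is exact
by default (the stricter reading), with a relaxed-endpoint option that
first aligns predicted to gold mentions by relaxed matching. Micro rows are
always computed from summed counts. Reports print at 4 decimal places.

`counts_from_prn` inverts a printed (precision, recall, support) row back to
integer counts and refuses inputs that no integer solution reproduces to
4 dp; it exists so published tables can be checked as arithmetic identities
when the underlying corpus is not available. Notably, the per-label counts
recovered this way sum exactly to the recovered micro-row counts for both
published NER criteria — a strong internal-consistency check.

## Action sequences

One step per REACTION_STEP mention, ordered by the verb's text offset (the
document order of the verbs); the step stores the verb span, so the sequence
stays aligned with the source text and `|steps|` always equals the action
count. Arguments are grouped by relation label and ordered by mention
offset; parameter values are carried verbatim — no unit parsing and no
chemistry inference (interpreting `reflux` as a boiling point is a
downstream concern). ARG0 containers render as an `in <container>` prefix.
The JSON rendering is schema-versioned and round-trips losslessly; nested
actions inside MODIFIER spans (parallel actions such as `with stirring`)
are not re-extracted, by schema design.

## The synthetic corpus generator

The real corpus is not redistributable, so the generator produces
structurally faithful stand-ins: per-roleset passive-voice sentence
templates, entity slots filled from a small vocabulary with parenthesized
amounts kept in-span, parameters emitted under the first-mention policy,
and relation labels always consistent with the head's roleset slots (an
`adversarial_roleset_args` switch deliberately emits ARG2 on `mix` for
validator testing). Default verb weights are the per-verb occurrence totals
observed in real procedures (add 204, stir 143, charge 106, … contain 1),
reproducing the heavy skew of synthesis vocabulary. The vocabulary
deliberately includes the annotation schema's canonical edge cases —
`room temperature (23 °C)`, `between 0 °C and 5 °C`, `ice/water`,
`overnight`, `internal temperature`, the amounts-and-coreference string —
so every annotation rule is exercised.

Noise flags emulate source-journal quirks: `note_refs` inserts `(Note n)` /
`(Figure n)` strings (gold offsets are computed on the noisy text, so the
stripping + offset-map path is exercised); `repeated_params` appends a
sentence reusing an already-annotated time value, unannotated per policy;
`workup_tail` appends unannotated workup sentences whose verbs partially
collide with the registry (*washed*), reproducing the boundary failure.

All randomness comes from one `random.Random(seed)` stream; the seed is
recorded in document metadata and identical configs yield byte-identical
corpora. Splits are procedure-level: dev and test each get
`floor(n·part/total)` documents after a seeded shuffle, the remainder goes
to train (112 documents at 8:1:1 → 90/11/11).

**What passing tests show, and what they do not.** The templates are inside
the rule baseline's pattern coverage *by construction*, so the baseline's
F = 1.0 on noise-free generated corpora is a parameter-recovery check of
the whole chain (generation → serialization → tagging → pairing →
classification → filtering), not a claim about real text. Real procedures
have free word order, coordination, anaphora, nested clauses and an open
vocabulary, none of which the generator models; measured scores on real
corpora are the published tables' concern, reproduced here only as
arithmetic identities.

## Numerical and interface conventions

* Sizes used by default checks: 20–200 generated documents, 3–8 sentences
  each; the full test suite and the acceptance script each run in seconds
  on one CPU.
* Mention ids are canonicalized by span start on serialization; relation
  ids by (head, tail, label). Ties cannot occur between generated spans.
* Discontinuous mentions are parsed and serialized (brat fragment syntax,
  fragments space-joined in the surface), but the generator emits only
  contiguous spans.
* Validation severity: structural violations (span bounds/order, surface
  mismatch, dangling references, label-incompatible relations, duplicates,
  ARG0 off *contain*) are errors; roleset mismatches and unresolved verbs
  are warnings.
* The CLI exits 0 on success, 1 when validation finds errors, 2 on usage
  errors; logs go to stderr, data to stdout or files; output trees include
  a `manifest.json` (command, seed, inputs, version, timestamp).
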