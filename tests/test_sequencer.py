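import random

import pytest

from synthroles.schema import EntityLabel
from synthroles.sequencer import (
    build_sequence,
    parse_json,
    render_json,
    render_text,
)

from conftest import make_doc


def test_two_step_sequence(two_step_doc, registry):
    seq = build_sequence(two_step_doc, registry)
    assert len(seq) == 2
    s1, s2 = seq.steps
    assert (s1.ordinal, s1.lemma, s1.roleset_id) == (1, "add", "add.01")
    assert s1.arg1 == ["A (1 g)"] and s1.arg2 == ["B (5 mL)"]
    assert s2.lemma == "stir" and s2.arg1 == ["the mixture"]
    assert s2.params == [(EntityLabel.TEMPERATURE, "0 °C"),
                         (EntityLabel.TIME, "2 h")]
    text = render_text(seq)
    lines = text.splitlines()
    assert lines[0].startswith("1. Add") and lines[1].startswith("2. Stir")
    assert "→ B (5 mL)" in lines[0]
    assert "(TEMPERATURE: 0 °C, TIME: 2 h)" in lines[1]


def test_empty_document_gives_empty_sequence(registry):
    doc = make_doc("No actions here.", [])
    seq = build_sequence(doc, registry)
    assert len(seq) == 0
    assert render_text(seq) == ""
    assert parse_json(render_json(seq)).steps == []


def test_roleset_inconsistent_arg_kept_with_warning(registry):
    doc = make_doc(
        "THF was mixed with dichloromethane (50 mL).",
        [("ENTITY", "THF"), ("REACTION_STEP", "mixed"),
         ("ENTITY", "dichloromethane (50 mL)")],
        [("ARG1", "T2", "T1"), ("ARG2", "T2", "T3")],
    )
    (step,) = build_sequence(doc, registry).steps
    assert step.arg2 == ["dichloromethane (50 mL)"]  # data never dropped
    assert "arg-not-in-roleset:ARG2" in step.warnings
    assert render_text(build_sequence(doc, registry)).rstrip().endswith("[!]")


def test_unresolved_verb_warns(registry):
    doc = make_doc("It was sonicated.", [("REACTION_STEP", "sonicated")])
    (step,) = build_sequence(doc, registry).steps
    assert step.roleset_id is None
    assert "unresolved-lemma" in step.warnings


def test_contain_renders_container_prefix(registry):
    doc = make_doc(
        "The flask contains DMF.",
        [("ENTITY", "The flask"), ("REACTION_STEP", "contains"), ("ENTITY", "DMF")],
        [("ARG0", "T2", "T1"), ("ARG1", "T2", "T3")],
    )
    line = render_text(build_sequence(doc, registry)).splitlines()[0]
    assert line.startswith("1. Contain in The flask")


def test_step_count_equals_action_count(corpus20, registry):
    for doc in corpus20:
        seq = build_sequence(doc, registry)
        n_actions = sum(
            1 for m in doc.mentions if m.label == EntityLabel.REACTION_STEP
        )
        assert len(seq) == n_actions
        assert [s.ordinal for s in seq.steps] == list(range(1, n_actions + 1))
        starts = [s.source_span.start for s in seq.steps]
        assert starts == sorted(starts)
        # traceability: every argument surface is an exact slice of some mention
        surfaces = {m.surface for m in doc.mentions}
        for s in seq.steps:
            for surf in s.arg0 + s.arg1 + s.arg2 + [p[1] for p in s.params]:
                assert surf in surfaces


def test_sequence_invariant_under_relation_permutation(two_step_doc, registry):
    rng = random.Random(3)
    base = build_sequence(two_step_doc, registry)
    for _ in range(5):
        rels = list(two_step_doc.relations)
        rng.shuffle(rels)
        shuffled = two_step_doc.replace(relations=rels)
        assert build_sequence(shuffled, registry).steps == base.steps


def test_json_roundtrip_preserves_unicode(corpus20, registry):
    for doc in corpus20[:10]:
        seq = build_sequence(doc, registry)
        again = parse_json(render_json(seq))
        assert again.doc_id == seq.doc_id and again.steps == seq.steps
    payload = render_json(build_sequence(corpus20[0], registry))
    assert "\\u" not in payload  # °C, – etc. stay literal


def test_parse_json_rejects_unknown_version():
    with pytest.raises(ValueError):
        parse_json('{"schema_version": "99", "doc_id": "d", "steps": []}')
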