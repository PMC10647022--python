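import pytest

from synthroles.brat import (
    ExportError,
    ParseError,
    export_iob2,
    export_relation_instances,
    iob2_to_conll,
    normalize_ids,
    parse_standoff,
    serialize_standoff,
    split_sentences,
    strip_note_refs,
    tokenize,
)
from synthroles.schema import EntityLabel, TextSpan

from conftest import make_doc


# --------------------------- standoff parsing ---------------------------

def test_parse_simple_records():
    text = "DMF was added to the flask."
    ann = (
        "T1\tENTITY 0 3\tDMF\n"
        "T2\tREACTION_STEP 8 13\tadded\n"
        "R1\tARG1 Arg1:T2 Arg2:T1\n"
    )
    doc = parse_standoff(text, ann)
    assert [m.label for m in doc.mentions] == [EntityLabel.ENTITY,
                                               EntityLabel.REACTION_STEP]
    assert doc.mentions[1].surface == "added"
    (rel,) = doc.relations
    assert (rel.head, rel.tail, rel.label.value) == ("T2", "T1", "ARG1")


def test_parse_discontinuous_mention():
    text = "added DMF slowly"
    ann = "T1\tREACTION_STEP 0 5;10 16\tadded slowly\n"
    doc = parse_standoff(text, ann)
    assert doc.mentions[0].spans == (TextSpan(0, 5), TextSpan(10, 16))


@pytest.mark.parametrize(
    "ann",
    [
        "T1\tENTITY 0 3\tXXX\n",               # surface mismatch
        "T1\tSOLVENT 0 3\tDMF\n",              # unknown label
        "R1\tARG9 Arg1:T1 Arg2:T2\n",          # unknown relation label
        "Q1\tENTITY 0 3\tDMF\n",               # unsupported record type
    ],
)
def test_parse_errors_name_the_record(ann):
    with pytest.raises(ParseError):
        parse_standoff("DMF was added.", ann)


def test_roundtrip_on_generated_corpus(corpus20):
    for doc in corpus20:
        txt, ann = serialize_standoff(doc)
        again = parse_standoff(txt, ann, doc.doc_id)
        norm = normalize_ids(doc)
        assert again.text == norm.text
        assert again.mentions == norm.mentions
        assert again.relations == norm.relations
        # serialization is canonical: a second pass is byte-identical
        assert serialize_standoff(again) == (txt, ann)


# --------------------------- preprocessing ---------------------------

def test_strip_note_refs_examples():
    cleaned, _ = strip_note_refs("anhydrous CH2Cl2 (150 mL) (Note 11) (Figure 1)")
    assert cleaned == "anhydrous CH2Cl2 (150 mL)"
    untouched = "12-aminododecanolactam (1) (9.00 g, 45.6 mmol, 1.00 equiv)"
    cleaned2, omap2 = strip_note_refs(untouched)
    assert cleaned2 == untouched
    assert [omap2.to_original(i) for i in range(3)] == [0, 1, 2]
    cleaned3, _ = strip_note_refs("X (Notes 3 and 5) and Y (Notes 3–5).")
    assert cleaned3 == "X and Y."


def test_offset_map_points_at_identical_characters():
    original = "stir (Note 1) for 2 h (Figure 2) at 0 °C (Note 3)."
    cleaned, omap = strip_note_refs(original)
    assert cleaned == "stir for 2 h at 0 °C."
    for i, ch in enumerate(cleaned):
        assert original[omap.to_original(i)] == ch
    # spans map to the same surface
    span = TextSpan(cleaned.index("2 h"), cleaned.index("2 h") + 3)
    mapped = omap.map_span(span)
    assert original[mapped.start:mapped.end] == "2 h"


def test_split_sentences_basic_and_abbreviations():
    assert len(split_sentences("A was added. B was stirred.")) == 2
    spans = split_sentences("cooled to 0 °C. After 12 h, the mixture was stirred.")
    assert len(spans) == 2
    text = "NaH (1.00 equiv. of base) was added. The mixture was stirred."
    assert len(split_sentences(text)) == 2
    assert split_sentences("") == []


def test_split_sentences_not_inside_numbers():
    text = "DMF (0.5 M, 9.00 g) was added over 1.5 h. Then it was stirred."
    spans = split_sentences(text)
    assert len(spans) == 2
    assert text[spans[0].start:spans[0].end].endswith("1.5 h.")


@pytest.mark.parametrize(
    "text,tokens",
    [
        ("0 °C", ["0", "°C"]),
        ("14–15 h", ["14–15", "h"]),
        ("12-aminododecanolactam (1)", ["12-aminododecanolactam", "(", "1", ")"]),
        ("ice/water", ["ice/water"]),
        ("9.00 g, 45.6 mmol", ["9.00", "g", ",", "45.6", "mmol"]),
        ("−78 °C", ["−", "78", "°C"]),
    ],
)
def test_tokenizer_keeps_chemistry_tokens(text, tokens):
    assert [t.text for t in tokenize(text)] == tokens


# --------------------------- IOB2 export ---------------------------

def test_export_iob2_tracks(two_step_doc):
    action = export_iob2(two_step_doc, "action")
    tags = [row.tag for sent in action for row in sent]
    assert tags.count("B-REACTION_STEP") == 2
    assert all(t in {"O", "B-REACTION_STEP"} for t in tags)

    params = export_iob2(two_step_doc, "parameter")
    ptags = [row.tag for sent in params for row in sent]
    assert "B-TEMPERATURE" in ptags and "B-TIME" in ptags
    assert "B-ENTITY" not in ptags


def test_export_iob2_empty_doc_is_all_o():
    doc = make_doc("Nothing is annotated here.", [])
    rows = export_iob2(doc, "entity")
    assert all(row.tag == "O" for sent in rows for row in sent)


def test_export_iob2_crossing_sentence_boundary_fails():
    text = "DMF was added. Then stirred."
    doc = make_doc(text, [])
    from synthroles.schema import Mention
    doc.mentions.append(
        Mention("T1", EntityLabel.ENTITY, (TextSpan(10, 20),), text[10:20])
    )
    with pytest.raises(ExportError):
        export_iob2(doc, "entity")


def test_iob2_conll_format(two_step_doc):
    out = iob2_to_conll(export_iob2(two_step_doc, "action"))
    lines = [l for l in out.splitlines() if l]
    assert all("\t" in l for l in lines)


# --------------------------- relation instances ---------------------------

def test_instance_count_is_actions_times_others(two_step_doc):
    # 2 actions x 5 non-action mentions in one sentence
    instances = export_relation_instances(two_step_doc)
    assert len(instances) == 10
    golds = {(i.head_id, i.tail_id): i.gold_label for i in instances}
    assert golds[("T2", "T1")] == "ARG1"
    assert golds[("T2", "T3")] == "ARG2"
    assert golds[("T5", "T7")] == "ARGM"
    assert golds[("T2", "T4")] == "NONE"


def test_instance_markers_wrap_the_right_spans(two_step_doc):
    inst = next(
        i for i in export_relation_instances(two_step_doc)
        if (i.head_id, i.tail_id) == ("T2", "T1")
    )
    assert "[E1]added[/E1]" in inst.text
    assert "[E2]A (1 g)[/E2]" in inst.text
    assert inst.text.count("[E1]") == inst.text.count("[/E1]") == 1


def test_instance_count_invariant_on_corpus(corpus20):
    from synthroles.brat import split_sentences
    for doc in corpus20:
        instances = export_relation_instances(doc)
        expected = 0
        for sent in split_sentences(doc.text):
            inside = [m for m in doc.mentions if sent.contains(m.extent)]
            n_act = sum(1 for m in inside if m.label == EntityLabel.REACTION_STEP)
            expected += n_act * (len(inside) - n_act)
        assert len(instances) == expected
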