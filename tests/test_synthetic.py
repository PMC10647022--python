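from collections import Counter

import pytest

from synthroles.brat import parse_standoff, serialize_standoff
from synthroles.pipeline import Lexicons
from synthroles.rolesets import default_registry
from synthroles.schema import EntityLabel, RelationLabel, validate_document
from synthroles.synthetic import (
    ALL_ENTITY_PHRASES,
    GeneratorConfig,
    GeneratorError,
    NoiseFlags,
    SplitRatio,
    corpus_stats,
    generate,
    split_corpus,
    split_sizes,
    with_total_row,
    write_corpus,
)


def test_generated_documents_validate_clean(corpus20, registry):
    assert len(corpus20) == 20
    for doc in corpus20:
        report = validate_document(doc, registry)
        assert report.issues == [], (doc.doc_id, report.issues)


def test_generation_is_deterministic():
    a = generate(GeneratorConfig(seed=13, n_procedures=6))
    b = generate(GeneratorConfig(seed=13, n_procedures=6))
    assert [serialize_standoff(d) for d in a] == [serialize_standoff(d) for d in b]
    c = generate(GeneratorConfig(seed=14, n_procedures=6))
    assert [d.text for d in a] != [d.text for d in c]


def test_default_weights_make_add_most_frequent(registry):
    docs = generate(GeneratorConfig(seed=1, n_procedures=60))
    lemmas = Counter()
    for d in docs:
        for m in d.mentions:
            if m.label == EntityLabel.REACTION_STEP:
                lemmas[registry.resolve(m.surface).lemma] += 1
    ranked = [lemma for lemma, _ in lemmas.most_common()]
    assert ranked[0] == "add"
    assert "stir" in ranked[:2]


def test_unknown_lemma_in_weights_rejected():
    with pytest.raises(GeneratorError):
        generate(GeneratorConfig(verb_weights={"sonicate": 5}))
    with pytest.raises(GeneratorError):
        generate(GeneratorConfig(verb_weights={"add": 0}))


def test_generator_vocabulary_is_inside_entity_lexicon():
    lexicon = {p.lower() for p in Lexicons.load().entities}
    for phrase in ALL_ENTITY_PHRASES:
        assert phrase.lower() in lexicon, phrase


def test_adversarial_flag_produces_roleset_warning(registry):
    cfg = GeneratorConfig(seed=0, n_procedures=40,
                          verb_weights={"mix": 5, "add": 1},
                          adversarial_roleset_args=True)
    docs = generate(cfg)
    warned = [
        w
        for d in docs
        for w in validate_document(d, registry).warnings
        if w.code == "arg-not-in-roleset"
    ]
    assert warned
    assert all(validate_document(d, registry).ok for d in docs)


def test_note_refs_inserted_outside_annotations(registry):
    docs = generate(GeneratorConfig(seed=4, n_procedures=15,
                                    noise=NoiseFlags(note_refs=True)))
    texts = " ".join(d.text for d in docs)
    assert "(Note" in texts
    for d in docs:
        assert validate_document(d, registry).issues == []
        for m in d.mentions:
            assert "(Note" not in m.surface and "(Figure" not in m.surface


def test_workup_tail_is_unannotated(registry):
    docs = generate(GeneratorConfig(seed=4, n_procedures=10,
                                    noise=NoiseFlags(workup_tail=True)))
    tailed = [d for d in docs if "organic layers" in d.text
              or "chromatography" in d.text or "evaporated" in d.text]
    assert tailed
    for d in tailed:
        for m in d.mentions:
            assert m.surface not in {"purified", "evaporated", "dried"}


def test_roundtrip_through_files(tmp_path, corpus20):
    write_corpus(corpus20[:4], tmp_path)
    for doc in corpus20[:4]:
        txt = (tmp_path / "all" / f"{doc.doc_id}.txt").read_text(encoding="utf-8")
        ann = (tmp_path / "all" / f"{doc.doc_id}.ann").read_text(encoding="utf-8")
        again = parse_standoff(txt, ann, doc.doc_id)
        assert serialize_standoff(again) == serialize_standoff(doc)


# ------------------------------ splits ------------------------------

@pytest.mark.parametrize(
    "n,expected",
    [(112, (90, 11, 11)), (10, (8, 1, 1)), (23, (19, 2, 2))],
)
def test_split_sizes(n, expected):
    assert split_sizes(n) == expected


def test_split_corpus_is_disjoint_and_exhaustive(corpus20):
    train, dev, test = split_corpus(corpus20, seed=5)
    assert (len(train), len(dev), len(test)) == (16, 2, 2)
    ids = [d.doc_id for d in train + dev + test]
    assert sorted(ids) == sorted(d.doc_id for d in corpus20)
    assert len(set(ids)) == len(ids)
    assert {d.split for d in train} == {"train"}
    # deterministic given the seed
    train2, _, _ = split_corpus(corpus20, seed=5)
    assert [d.doc_id for d in train2] == [d.doc_id for d in train]


def test_split_ratio_validation():
    with pytest.raises(ValueError):
        SplitRatio(1, 2, 1)
    with pytest.raises(ValueError):
        SplitRatio(8, 0, 1)


# ------------------------------ statistics ------------------------------

def test_corpus_stats_totals_are_column_sums(corpus20):
    train, dev, test = split_corpus(corpus20, seed=0)
    stats = corpus_stats(train + dev + test)
    for df in (stats.ner, stats.re):
        assert set(df.columns) == {"train", "dev", "test"}
        for col in df.columns:
            assert df.loc["total", col] == df.loc[df.index != "total", col].sum()
    assert stats.procedures.loc["total", "procedures"] == 20
    n_mentions = sum(len(d.mentions) for d in corpus20)
    assert stats.ner.loc["total"].sum() == n_mentions


def test_corpus_stats_empty():
    stats = corpus_stats([])
    assert (stats.ner.values == 0).all()
    assert (stats.re.values == 0).all()


def test_with_total_row_matches_printed_label_tables():
    import pandas as pd
    ner = pd.DataFrame(
        {"train": [590, 900, 225, 48, 218, 161]},
        index=["REACTION_STEP", "ENTITY", "TEMPERATURE", "TEMP_TARGET",
               "TIME", "MODIFIER"],
    )
    assert with_total_row(ner).loc["total", "train"] == 2142
    re_df = pd.DataFrame({"train": [611, 361, 648, 1]},
                         index=["ARG1", "ARG2", "ARGM", "ARG0"])
    assert with_total_row(re_df).loc["total", "train"] == 1621
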