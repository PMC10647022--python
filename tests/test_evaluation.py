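import itertools
import random

import pytest

from synthroles.evaluation import (
    EvalCounts,
    counts_from_prn,
    evaluate_ner,
    evaluate_re,
    match_mentions,
    prf,
    verb_recall,
)
from synthroles.schema import EntityLabel, Mention, TextSpan
from synthroles.synthetic import GeneratorConfig, generate, split_corpus

from conftest import make_doc


def _mention(i, label, start, end):
    return Mention(f"M{i}", EntityLabel(label), (TextSpan(start, end),), "x" * (end - start))


# ------------------------------ prf ------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        (EvalCounts(54, 3, 5), (0.9474, 0.9153, 0.9310)),
        (EvalCounts(0, 0, 0), (0.0, 0.0, 0.0)),
        (EvalCounts(5, 0, 0), (1.0, 1.0, 1.0)),
        (EvalCounts(0, 3, 2), (0.0, 0.0, 0.0)),
    ],
)
def test_prf(counts, expected):
    assert tuple(round(v, 4) for v in prf(counts)) == expected


# ------------------------------ matching ------------------------------

def test_exact_vs_relaxed_offset_shift():
    gold = [_mention(1, "ENTITY", 10, 25)]
    pred = [_mention(2, "ENTITY", 12, 25)]
    exact = match_mentions(gold, pred, "exact")["ENTITY"]
    assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
    relaxed = match_mentions(gold, pred, "relaxed")["ENTITY"]
    assert (relaxed.tp, relaxed.fp, relaxed.fn) == (1, 0, 0)


def test_overlap_with_wrong_label_never_matches():
    gold = [_mention(1, "ENTITY", 0, 5)]
    pred = [_mention(2, "TIME", 0, 5)]
    counts = match_mentions(gold, pred, "relaxed")
    assert counts["ENTITY"].fn == 1 and counts["TIME"].fp == 1


def test_one_to_one_matching_two_preds_one_gold():
    gold = [_mention(1, "ENTITY", 0, 10)]
    pred = [_mention(2, "ENTITY", 0, 4), _mention(3, "ENTITY", 5, 10)]
    counts = match_mentions(gold, pred, "relaxed")["ENTITY"]
    assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)
    many = match_mentions(gold, pred, "relaxed", one_to_one=False)["ENTITY"]
    assert (many.tp, many.fp, many.fn) == (2, 0, 0)


def _random_disjoint_spans(rng, max_n=6):
    """Disjoint spans as produced by per-label annotation or IOB2 decoding."""
    spans = []
    pos = 0
    for _ in range(rng.randint(0, max_n)):
        pos += rng.randint(0, 4)
        width = rng.randint(1, 6)
        spans.append((pos, pos + width))
        pos += width
    return spans


def _bruteforce_max_matching(gold, pred):
    def overlap(g, p):
        return g[0] < p[1] and p[0] < g[1]

    best = 0
    idx = range(len(gold))
    for r in range(min(len(gold), len(pred)), -1, -1):
        for combo in itertools.permutations(idx, r):
            subset = itertools.combinations(range(len(pred)), r)
            for preds in subset:
                if all(overlap(gold[g], pred[p]) for g, p in zip(combo, preds)):
                    return r
    return best


def test_greedy_relaxed_matching_is_maximum_on_disjoint_sets():
    rng = random.Random(42)
    for _ in range(150):
        gold_spans = _random_disjoint_spans(rng)
        pred_spans = _random_disjoint_spans(rng)
        gold = [_mention(i, "ENTITY", s, e) for i, (s, e) in enumerate(gold_spans)]
        pred = [_mention(100 + i, "ENTITY", s, e)
                for i, (s, e) in enumerate(pred_spans)]
        counts = match_mentions(gold, pred, "relaxed")
        greedy_tp = counts["ENTITY"].tp if counts else 0
        assert greedy_tp == _bruteforce_max_matching(gold_spans, pred_spans)


# ------------------------------ corpus-level ------------------------------

def test_gold_vs_gold_is_perfect(corpus20):
    ner = evaluate_ner(corpus20, corpus20, "exact")
    for label, row in ner.rows.items():
        if row.support:
            assert (row.precision, row.recall, row.fscore) == (1.0, 1.0, 1.0)
    rr = evaluate_re(corpus20, corpus20)
    assert rr["all"].fscore == 1.0


def test_micro_row_is_summed_counts(corpus20):
    # perturb predictions by dropping mentions
    rng = random.Random(0)
    preds = []
    for doc in corpus20:
        kept = [m for m in doc.mentions if rng.random() > 0.2]
        preds.append(doc.replace(mentions=kept, relations=[]))
    report = evaluate_ner(corpus20, preds, "exact")
    total = EvalCounts()
    for label, counts in report.counts.items():
        if label != "all":
            total = total + counts
    assert report.counts["all"] == total


def test_relaxed_f_dominates_exact_f(corpus20):
    rng = random.Random(1)
    preds = []
    for doc in corpus20:
        mentions = []
        for m in doc.mentions:
            s = m.spans[0]
            start = max(0, s.start + rng.choice([-2, -1, 0, 1]))
            end = min(len(doc.text), max(start + 1, s.end + rng.choice([-1, 0, 1])))
            mentions.append(Mention(m.id, m.label, (TextSpan(start, end),),
                                    doc.text[start:end]))
        preds.append(doc.replace(mentions=mentions, relations=[]))
    exact = evaluate_ner(corpus20, preds, "exact")
    relaxed = evaluate_ner(corpus20, preds, "relaxed")
    for label in exact.rows:
        assert relaxed[label].fscore >= exact[label].fscore


def test_doc_id_mismatch_raises(corpus20):
    with pytest.raises(ValueError):
        evaluate_ner(corpus20[:3], corpus20[1:4])


# ------------------------------ counts_from_prn --------------------------

@pytest.mark.parametrize(
    "p,r,n,expected",
    [
        (0.9231, 1.0000, 24, (24, 2, 0)),
        (1.0, 1.0, 7, (7, 0, 0)),
        (0.8932, 0.9200, 100, (92, 11, 8)),
    ],
)
def test_counts_from_prn(p, r, n, expected):
    c = counts_from_prn(p, r, n)
    assert (c.tp, c.fp, c.fn) == expected


def test_counts_from_prn_rejects_inconsistent_inputs():
    with pytest.raises(ValueError):
        counts_from_prn(0.5, 0.9999, 3)


# ------------------------------ relation eval ----------------------------

def test_evaluate_re_counts(two_step_doc):
    # drop one relation and add a wrong one
    broken = two_step_doc.replace(relations=list(two_step_doc.relations[:-1]))
    report = evaluate_re([two_step_doc], [broken])
    assert report["all"].recall < 1.0 and report["all"].precision == 1.0


def test_evaluate_re_dangling_endpoint_raises(two_step_doc):
    from synthroles.schema import Relation, RelationLabel
    broken = two_step_doc.replace(
        relations=[Relation("R1", RelationLabel.ARG1, "T2", "T99")]
    )
    with pytest.raises(ValueError):
        evaluate_re([two_step_doc], [broken])


# ------------------------------ verb recall ------------------------------

def test_verb_recall_perfect_and_missing(corpus20, registry):
    df = verb_recall(corpus20, corpus20, registry)
    assert (df["recall"] == 1.0).all()
    assert df["n_gold"].sum() == sum(
        1 for d in corpus20 for m in d.mentions
        if m.label == EntityLabel.REACTION_STEP
    )
    # remove every 'stirred' prediction -> stir recall 0
    preds = [
        d.replace(mentions=[m for m in d.mentions if m.surface != "stirred"],
                  relations=[])
        for d in corpus20
    ]
    df2 = verb_recall(corpus20, preds, registry)
    assert df2.loc["stir", "recall"] == 0.0
    assert df2.loc["add", "recall"] == 1.0


def test_verb_recall_split_counts(registry):
    docs = generate(GeneratorConfig(seed=9, n_procedures=10))
    train, dev, test = split_corpus(docs, seed=9)
    df = verb_recall(test, test, registry, corpus_docs=train + dev + test)
    count_cols = [c for c in df.columns if c.startswith("n_") and c != "n_gold"]
    assert df["n_gold"].equals(df["n_test"])
    assert set(count_cols) <= {"n_train", "n_dev", "n_test"}
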