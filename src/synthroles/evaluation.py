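"""Precision/recall/F scoring for span (NER) and relation (RE) predictions.

Span scoring supports two criteria:

* ``exact`` — a predicted mention is a true positive iff its span set and
  label both equal a gold mention's;
* ``relaxed`` — at least one character of overlap with the same label counts,
  under one-to-one assignment: predictions are processed in start-offset
  order and each claims the earliest-ending unmatched overlapping gold
  mention.  Because same-label spans on either side are mutually disjoint in
  this corpus (annotation policy, and IOB2 decoding can produce nothing
  else), this greedy assignment attains the maximum bipartite matching; a
  many-to-one variant is available behind ``one_to_one=False``.

Relation scoring: a predicted relation is a true positive iff its head and
tail mentions match gold mentions (exact span + entity label by default) and
the relation label agrees.  All micro rows are computed from summed counts.
The 0/0 convention for any metric is 0.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .rolesets import RolesetRegistry, default_registry
from .schema import (
    AnnotatedDocument,
    EntityLabel,
    Mention,
    RelationLabel,
)

NER_LABEL_ORDER = [
    EntityLabel.REACTION_STEP,
    EntityLabel.ENTITY,
    EntityLabel.TEMPERATURE,
    EntityLabel.TEMP_TARGET,
    EntityLabel.TIME,
    EntityLabel.MODIFIER,
]
RE_LABEL_ORDER = [
    RelationLabel.ARG1,
    RelationLabel.ARG2,
    RelationLabel.ARGM,
    RelationLabel.ARG0,
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @property
    def support(self) -> int:
        return self.tp + self.fn


def prf(c: EvalCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); any 0/0 is 0 by convention."""
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass(frozen=True)
class EvalRow:
    precision: float
    recall: float
    fscore: float
    support: int


@dataclass
class EvalReport:
    """Per-label rows plus a micro-averaged ``all`` row (summed counts)."""

    counts: dict[str, EvalCounts]

    @property
    def rows(self) -> dict[str, EvalRow]:
        out = {}
        for label, c in self.counts.items():
            p, r, f = prf(c)
            out[label] = EvalRow(p, r, f, c.support)
        return out

    def __getitem__(self, label: str) -> EvalRow:
        return self.rows[label]

    def to_tsv(self) -> str:
        lines = ["label\tprecision\trecall\tfscore\tsupport"]
        for label, row in self.rows.items():
            lines.append(
                f"{label}\t{row.precision:.4f}\t{row.recall:.4f}"
                f"\t{row.fscore:.4f}\t{row.support}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            label: {
                "precision": round(row.precision, 4),
                "recall": round(row.recall, 4),
                "fscore": round(row.fscore, 4),
                "support": row.support,
            }
            for label, row in self.rows.items()
        }
        return json.dumps(payload, indent=2)


def _with_micro(counts: dict[str, EvalCounts], order: Sequence) -> EvalReport:
    full = {label.value: counts.get(label.value, EvalCounts()) for label in order}
    total = EvalCounts()
    for c in full.values():
        total = total + c
    full["all"] = total
    return EvalReport(full)


# ---------------------------------------------------------------------------
# mention matching
# ---------------------------------------------------------------------------

def _span_key(m: Mention):
    return tuple((s.start, s.end) for s in m.spans)


def _overlaps(a: Mention, b: Mention) -> bool:
    return any(sa.overlaps(sb) for sa in a.spans for sb in b.spans)


def match_mentions(
    gold: Sequence[Mention],
    pred: Sequence[Mention],
    criterion: str = "exact",
    one_to_one: bool = True,
) -> dict[str, EvalCounts]:
    """Per-label TP/FP/FN for one document's mentions."""
    if criterion not in {"exact", "relaxed"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    out: dict[str, EvalCounts] = {}
    labels = {m.label for m in gold} | {m.label for m in pred}
    for label in labels:
        g = sorted((m for m in gold if m.label == label), key=_span_key)
        p = sorted((m for m in pred if m.label == label), key=_span_key)
        if criterion == "exact":
            gc = Counter(_span_key(m) for m in g)
            pc = Counter(_span_key(m) for m in p)
            tp = sum(min(gc[k], pc[k]) for k in gc)
            fp, fn = len(p) - tp, len(g) - tp
        elif one_to_one:
            # predictions in start order claim the earliest-ending unmatched
            # overlapping gold mention
            taken = [False] * len(g)
            tp = 0
            for pm in p:
                best = None
                for idx, gm in enumerate(g):
                    if taken[idx] or not _overlaps(pm, gm):
                        continue
                    if best is None or gm.end < g[best].end:
                        best = idx
                if best is not None:
                    taken[best] = True
                    tp += 1
            fp, fn = len(p) - tp, len(g) - tp
        else:
            tp = sum(1 for pm in p if any(_overlaps(pm, gm) for gm in g))
            fp = len(p) - tp
            fn = sum(1 for gm in g if not any(_overlaps(gm, pm) for pm in p))
        out[label.value] = EvalCounts(tp, fp, fn)
    return out


def _paired_docs(gold_docs, pred_docs):
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(gold_by_id) != set(pred_by_id):
        raise ValueError(
            "gold/pred document ids differ: "
            f"{sorted(set(gold_by_id) ^ set(pred_by_id))}"
        )
    for doc_id in sorted(gold_by_id):
        yield gold_by_id[doc_id], pred_by_id[doc_id]


def evaluate_ner(
    gold_docs: Iterable[AnnotatedDocument],
    pred_docs: Iterable[AnnotatedDocument],
    criterion: str = "exact",
    one_to_one: bool = True,
) -> EvalReport:
    """Corpus-level NER report: per-label rows plus the micro ``all`` row."""
    totals: dict[str, EvalCounts] = {}
    for g, p in _paired_docs(gold_docs, pred_docs):
        for label, c in match_mentions(
            g.mentions, p.mentions, criterion, one_to_one
        ).items():
            totals[label] = totals.get(label, EvalCounts()) + c
    return _with_micro(totals, NER_LABEL_ORDER)


def evaluate_re(
    gold_docs: Iterable[AnnotatedDocument],
    pred_docs: Iterable[AnnotatedDocument],
    entity_source: str = "gold",
    endpoint_match: str = "exact",
) -> EvalReport:
    """Corpus-level RE report.

    ``entity_source`` records whether predictions were made over gold or
    predicted mentions (the matching rule is the same); ``endpoint_match``
    selects how predicted endpoints are identified with gold mentions:
    ``exact`` (default, the stricter reading) or ``relaxed`` (endpoints
    aligned by the one-to-one relaxed mention matching first).
    """
    if entity_source not in {"gold", "predicted"}:
        raise ValueError(f"unknown entity_source {entity_source!r}")
    if endpoint_match not in {"exact", "relaxed"}:
        raise ValueError(f"unknown endpoint_match {endpoint_match!r}")
    totals: dict[str, EvalCounts] = {}
    for g, p in _paired_docs(gold_docs, pred_docs):
        gold_rel = _relation_keys(g, endpoint_match, other=p)
        pred_rel = _relation_keys(p, endpoint_match, other=g, reverse_align=True)
        labels = {k[0] for k in gold_rel} | {k[0] for k in pred_rel}
        for label in labels:
            gc = Counter(k for k in gold_rel if k[0] == label)
            pc = Counter(k for k in pred_rel if k[0] == label)
            tp = sum(min(gc[k], pc[k]) for k in gc)
            counts = EvalCounts(tp, sum(pc.values()) - tp, sum(gc.values()) - tp)
            totals[label] = totals.get(label, EvalCounts()) + counts
    return _with_micro(totals, RE_LABEL_ORDER)


def _relation_keys(doc, endpoint_match, other=None, reverse_align=False):
    """Relation triples keyed by endpoint identity.

    With exact endpoints the key is (label, head span+label, tail span+label).
    With relaxed endpoints, predicted mentions are first aligned one-to-one to
    gold mentions by relaxed matching and keyed by their aligned partner.
    """
    by_id = {m.id: m for m in doc.mentions}
    align = {}
    if endpoint_match == "relaxed" and other is not None and reverse_align:
        for label in {m.label for m in doc.mentions}:
            g = sorted((m for m in other.mentions if m.label == label),
                       key=_span_key)
            p = sorted((m for m in doc.mentions if m.label == label),
                       key=_span_key)
            taken = [False] * len(g)
            for pm in p:
                best = None
                for idx, gm in enumerate(g):
                    if taken[idx] or not _overlaps(pm, gm):
                        continue
                    if best is None or gm.end < g[best].end:
                        best = idx
                if best is not None:
                    taken[best] = True
                    align[pm.id] = g[best]

    keys = []
    for r in doc.relations:
        head = by_id.get(r.head)
        tail = by_id.get(r.tail)
        if head is None or tail is None:
            raise ValueError(
                f"relation {r.id} in {doc.doc_id} has dangling endpoints"
            )
        head = align.get(head.id, head)
        tail = align.get(tail.id, tail)
        keys.append(
            (
                r.label.value,
                (head.label.value, _span_key(head)),
                (tail.label.value, _span_key(tail)),
            )
        )
    return keys


# ---------------------------------------------------------------------------
# printed-table utilities and per-verb recall
# ---------------------------------------------------------------------------

def counts_from_prn(p: float, r: float, n: int) -> EvalCounts:
    """Recover integer (tp, fp, fn) from printed precision/recall/support.

    tp = round(r·n), fp = round(tp/p) − tp, fn = n − tp; the recovered counts
    must reproduce the printed precision and recall to 4 decimal places,
    otherwise the inputs are inconsistent and a ValueError is raised.
    """
    if not (0 < p <= 1 and 0 < r <= 1 and n > 0):
        raise ValueError("need 0 < p,r <= 1 and n > 0")
    tp = round(r * n)
    fp = round(tp / p) - tp
    fn = n - tp
    counts = EvalCounts(tp, fp, fn)
    p2, r2, _ = prf(counts)
    if round(p2, 4) != round(p, 4) or round(r2, 4) != round(r, 4):
        raise ValueError(
            f"(p={p}, r={r}, n={n}) is not consistent with integer counts "
            f"{counts}"
        )
    return counts


def verb_recall(
    gold_docs: Iterable[AnnotatedDocument],
    pred_docs: Iterable[AnnotatedDocument],
    registry: Optional[RolesetRegistry] = None,
    corpus_docs: Optional[Iterable[AnnotatedDocument]] = None,
) -> pd.DataFrame:
    """Per-lemma recall of REACTION_STEP mentions (exact span match).

    Gold action mentions are grouped by their resolved lemma (unresolved
    surfaces group under their lowercased surface).  When ``corpus_docs`` is
    given, per-split occurrence counts are added from those documents' split
    metadata.  Returns a DataFrame indexed by lemma, sorted by gold count.
    """
    registry = registry or default_registry()

    def lemma_of(m: Mention) -> str:
        rs = registry.resolve(m.surface)
        return rs.lemma if rs is not None else m.surface.lower()

    found: Counter = Counter()
    total: Counter = Counter()
    for g, p in _paired_docs(gold_docs, pred_docs):
        pred_keys = {
            _span_key(m)
            for m in p.mentions
            if m.label == EntityLabel.REACTION_STEP
        }
        for m in g.mentions:
            if m.label != EntityLabel.REACTION_STEP:
                continue
            lemma = lemma_of(m)
            total[lemma] += 1
            if _span_key(m) in pred_keys:
                found[lemma] += 1

    rows = {
        lemma: {"recall": found[lemma] / total[lemma], "n_gold": total[lemma]}
        for lemma in total
    }
    if corpus_docs is not None:
        for doc in corpus_docs:
            split = doc.split or "all"
            for m in doc.mentions:
                if m.label != EntityLabel.REACTION_STEP:
                    continue
                lemma = lemma_of(m)
                if lemma not in rows:
                    continue
                rows[lemma][f"n_{split}"] = rows[lemma].get(f"n_{split}", 0) + 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    count_cols = [c for c in df.columns if c.startswith("n_")]
    df[count_cols] = df[count_cols].astype(int)
    return df.sort_values(["n_gold", "recall"], ascending=[False, False])
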