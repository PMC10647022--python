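"""brat standoff I/O, text preprocessing, and model-input export.

The corpus interchange format is brat v1.3 standoff: a raw ``.txt`` file plus
an ``.ann`` file of ``T`` (text-bound) and ``R`` (relation) records.  This
module also carries the deterministic text machinery the rest of the package
relies on:

* :func:`strip_note_refs` — removes the journal's parenthesized ``(Note n)`` /
  ``(Figure n)`` cross-references while keeping an offset map back to the
  original text;
* :func:`split_sentences` — a rule-based splitter with a fixed abbreviation
  list, pinned for reproducibility;
* :func:`tokenize` — a documented regex tokenizer (see :data:`TOKEN_RE`) that
  keeps decimal numbers, ranges (``14–15``), ``°C`` and hyphen/slash-joined
  chemical tokens intact;
* IOB2 and marked-pair exports used to train or drive sequence taggers and
  relation classifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .schema import (
    AnnotatedDocument,
    EntityLabel,
    Mention,
    PARAMETER_LABELS,
    Relation,
    RelationLabel,
    TextSpan,
    expected_surface,
)


class ParseError(ValueError):
    """Malformed standoff record."""


class ExportError(ValueError):
    """Annotation cannot be exported in the requested view."""


# ---------------------------------------------------------------------------
# standoff parsing / serialization
# ---------------------------------------------------------------------------

def parse_standoff(text: str, ann: str, doc_id: str = "doc") -> AnnotatedDocument:
    """Parse brat standoff content into an :class:`AnnotatedDocument`.

    ``T`` records carry a label, one or more ``;``-separated fragments and the
    covered surface (checked against the text); ``R`` records carry a relation
    label and two positional slots, ``Arg1:`` (head) and ``Arg2:`` (tail) —
    brat's slot names, unrelated to the ARG1/ARG2 relation types.
    ``#`` comment records are ignored.
    """
    mentions: list[Mention] = []
    relations: list[Relation] = []
    for lineno, raw in enumerate(ann.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        rec_id = line.split("\t", 1)[0]
        if rec_id.startswith("#"):
            continue
        if rec_id.startswith("T"):
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{doc_id}.ann:{lineno}: malformed T record {rec_id}")
            surface = parts[2] if len(parts) > 2 else ""
            head, _, span_str = parts[1].partition(" ")
            try:
                label = EntityLabel(head)
            except ValueError:
                raise ParseError(
                    f"{doc_id}.ann:{lineno}: unknown entity label {head!r} in {rec_id}"
                ) from None
            spans = []
            for frag in span_str.split(";"):
                try:
                    start_s, end_s = frag.split()
                    spans.append(TextSpan(int(start_s), int(end_s)))
                except ValueError:
                    raise ParseError(
                        f"{doc_id}.ann:{lineno}: bad span {frag!r} in {rec_id}"
                    ) from None
            want = expected_surface(text, spans)
            if surface != want:
                raise ParseError(
                    f"{doc_id}.ann:{lineno}: record {rec_id} surface {surface!r} "
                    f"does not match text {want!r}"
                )
            mentions.append(Mention(rec_id, label, tuple(spans), surface))
        elif rec_id.startswith("R"):
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{doc_id}.ann:{lineno}: malformed R record {rec_id}")
            fields = parts[1].split()
            if len(fields) != 3:
                raise ParseError(
                    f"{doc_id}.ann:{lineno}: R record {rec_id} needs LABEL Arg1: Arg2:"
                )
            try:
                label = RelationLabel(fields[0])
            except ValueError:
                raise ParseError(
                    f"{doc_id}.ann:{lineno}: unknown relation label {fields[0]!r} "
                    f"in {rec_id}"
                ) from None
            slots = {}
            for f in fields[1:]:
                name, _, ref = f.partition(":")
                slots[name] = ref
            if set(slots) != {"Arg1", "Arg2"}:
                raise ParseError(
                    f"{doc_id}.ann:{lineno}: R record {rec_id} slots must be "
                    "Arg1/Arg2"
                )
            relations.append(Relation(rec_id, label, slots["Arg1"], slots["Arg2"]))
        else:
            raise ParseError(
                f"{doc_id}.ann:{lineno}: unsupported record type {rec_id!r}"
            )
    return AnnotatedDocument(doc_id, text, mentions, relations)


def _mention_sort_key(m: Mention):
    return (m.start, m.end, m.label.value, m.id)


def normalize_ids(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Renumber mention/relation ids deterministically (by span start)."""
    mentions = sorted(doc.mentions, key=_mention_sort_key)
    id_map = {m.id: f"T{i}" for i, m in enumerate(mentions, 1)}
    new_mentions = [
        Mention(id_map[m.id], m.label, m.spans, m.surface) for m in mentions
    ]
    order = {new: i for i, new in enumerate(id_map.values())}
    rels = sorted(
        doc.relations,
        key=lambda r: (order[id_map[r.head]], order[id_map[r.tail]], r.label.value),
    )
    new_rels = [
        Relation(f"R{i}", r.label, id_map[r.head], id_map[r.tail])
        for i, r in enumerate(rels, 1)
    ]
    return doc.replace(mentions=new_mentions, relations=new_rels)


def serialize_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize to ``(txt content, ann content)``; inverse of parsing.

    Ids are renumbered in span order so serialization is canonical.
    """
    norm = normalize_ids(doc)
    lines = []
    for m in norm.mentions:
        span_str = ";".join(f"{s.start} {s.end}" for s in m.spans)
        lines.append(f"{m.id}\t{m.label.value} {span_str}\t{m.surface}")
    for r in norm.relations:
        lines.append(f"{r.id}\t{r.label.value} Arg1:{r.head} Arg2:{r.tail}")
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return norm.text, ann


def read_standoff(txt_path: Union[str, Path]) -> AnnotatedDocument:
    """Read a ``.txt``/``.ann`` pair given the path of either file."""
    txt_path = Path(txt_path)
    stem = txt_path.with_suffix("")
    text = stem.with_suffix(".txt").read_text(encoding="utf-8")
    ann_file = stem.with_suffix(".ann")
    ann = ann_file.read_text(encoding="utf-8") if ann_file.exists() else ""
    doc = parse_standoff(text, ann, doc_id=stem.name)
    parent = stem.parent.name
    if parent in {"train", "dev", "test"}:
        doc.split = parent
    return doc


def write_standoff(doc: AnnotatedDocument, directory: Union[str, Path]) -> Path:
    """Write ``<directory>/<doc_id>.txt`` and ``.ann``; returns the txt path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    text, ann = serialize_standoff(doc)
    txt_path = directory / f"{doc.doc_id}.txt"
    txt_path.write_text(text, encoding="utf-8")
    (directory / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")
    return txt_path


def read_corpus_dir(path: Union[str, Path]) -> list[AnnotatedDocument]:
    """Read every ``.txt``/``.ann`` pair under ``path`` (recursively)."""
    path = Path(path)
    docs = [read_standoff(p) for p in sorted(path.rglob("*.txt"))]
    if not docs:
        raise FileNotFoundError(f"no .txt files under {path}")
    return docs


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

#: Parenthesized journal cross-references: "(Note 3)", "(Notes 3 and 5)",
#: "(Notes 3–5)", "(Figure 1)".  One preceding space, when present, is
#: removed with the reference so no doubled space is left behind.
NOTE_REF_RE = re.compile(
    r" ?\((?:Notes?|Figures?|Figs?\.?)\s+\d+[a-z]?"
    r"(?:\s*(?:[-–,]\s*|and\s+)\d+[a-z]?)*\)"
)


@dataclass(frozen=True)
class OffsetMap:
    """Monotone map from cleaned-text offsets back to original offsets."""

    positions: tuple[int, ...]
    original_length: int

    def to_original(self, i: int) -> int:
        if i == len(self.positions):
            return self.positions[-1] + 1 if self.positions else self.original_length
        return self.positions[i]

    def map_span(self, span: TextSpan) -> TextSpan:
        """Map a cleaned-text span to the original text.

        The result is the contiguous original interval from the image of
        ``start`` to the image of ``end-1``; a span that straddles a removed
        region therefore re-includes it.
        """
        return TextSpan(self.positions[span.start], self.positions[span.end - 1] + 1)

    def __len__(self) -> int:
        return len(self.positions)


def strip_note_refs(text: str) -> tuple[str, OffsetMap]:
    """Remove Note/Figure cross-references; return cleaned text + offset map.

    Every other parenthesized group — amounts, coreference labels such as
    ``(1)``, inline temperatures — is left untouched.
    """
    pieces: list[str] = []
    kept: list[int] = []
    last = 0
    for m in NOTE_REF_RE.finditer(text):
        pieces.append(text[last : m.start()])
        kept.extend(range(last, m.start()))
        last = m.end()
    pieces.append(text[last:])
    kept.extend(range(last, len(text)))
    return "".join(pieces), OffsetMap(tuple(kept), len(text))


#: Tokens before a period that never end a sentence (lowercased, no dot).
ABBREVIATIONS = frozenset(
    {
        "equiv", "aq", "ca", "approx", "anhyd", "e.g", "i.e", "etc", "cf",
        "fig", "figs", "ref", "refs", "vs", "wt", "vol", "mp", "bp", "no",
        "dr", "mr", "prof", "st",
    }
)

_LAST_TOKEN_RE = re.compile(r"[\w°/.\-–]+$")


def split_sentences(text: str) -> list[TextSpan]:
    """Rule-based sentence spans (whitespace between sentences is dropped).

    A ``.``/``!``/``?`` ends a sentence when followed by whitespace and then
    an uppercase letter or digit, unless the preceding token is a known
    abbreviation or a single capital (an initial).  Periods inside numbers or
    immediately before a non-space character never split, which keeps tokens
    like ``0.5 M`` and ``1.00 equiv)`` whole.
    """
    spans: list[TextSpan] = []
    n = len(text)
    start = 0
    for m in re.finditer(r"[.!?]", text):
        i = m.start()
        j = i + 1
        if j < n and not text[j].isspace():
            continue
        while j < n and text[j].isspace():
            j += 1
        if j < n and not (text[j].isupper() or text[j].isdigit()):
            continue
        prev = _LAST_TOKEN_RE.search(text[start:i])
        if prev and text[i] == ".":
            tok = prev.group(0).rstrip(".")
            if tok.lower() in ABBREVIATIONS:
                continue
            if len(tok) == 1 and tok.isupper() and tok != "C":
                continue
        while start < i and text[start].isspace():
            start += 1
        if start < i + 1:
            spans.append(TextSpan(start, i + 1))
        start = j
    while start < n and text[start].isspace():
        start += 1
    if start < n:
        spans.append(TextSpan(start, n))
    return spans


#: The pinned tokenizer: maximal runs of word characters and ``°`` that may be
#: chained by ``-``/``–``/``/`` or a decimal point followed by digits; any
#: other non-space character is a token by itself.
TOKEN_RE = re.compile(r"[\w°]+(?:\.\d+)?(?:[-–/][\w°]+(?:\.\d+)?)*|\S")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Tokenize ``text``; offsets are absolute when ``offset`` is supplied."""
    return [
        Token(m.group(0), offset + m.start(), offset + m.end())
        for m in TOKEN_RE.finditer(text)
    ]


# ---------------------------------------------------------------------------
# IOB2 export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Iob2Row:
    token: str
    tag: str


TRACKS = {
    "action": frozenset({EntityLabel.REACTION_STEP}),
    "entity": frozenset({EntityLabel.ENTITY}),
    "parameter": PARAMETER_LABELS,
}


def check_iob2(tags: Sequence[str]) -> None:
    """Raise ValueError when a tag sequence violates the IOB2 constraint."""
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            if prev == "O" or prev[2:] != tag[2:]:
                raise ValueError(f"I-tag {tag} cannot follow {prev}")
        elif tag != "O" and not tag.startswith("B-"):
            raise ValueError(f"malformed tag {tag!r}")
        prev = tag


def export_iob2(
    doc: AnnotatedDocument, track: str
) -> list[list[Iob2Row]]:
    """Per-sentence IOB2 rows for one annotation track.

    ``track`` is one of ``action`` / ``entity`` / ``parameter``; only the
    labels of that track are emitted, every other token is ``O``.  A mention
    that crosses a sentence boundary is an export error.
    """
    if track not in TRACKS:
        raise ValueError(f"unknown track {track!r}")
    labels = TRACKS[track]
    sentences = split_sentences(doc.text)
    out: list[list[Iob2Row]] = []
    track_mentions = sorted(
        (m for m in doc.mentions if m.label in labels), key=_mention_sort_key
    )
    for sent in sentences:
        tokens = tokenize(doc.text[sent.start : sent.end], offset=sent.start)
        tags = ["O"] * len(tokens)
        for m in track_mentions:
            if m.end <= sent.start or m.start >= sent.end:
                continue
            if not sent.contains(m.extent):
                raise ExportError(
                    f"mention {m.id} crosses a sentence boundary in {doc.doc_id}"
                )
            first = True
            for k, tok in enumerate(tokens):
                hit = any(
                    tok.start < s.end and s.start < tok.end for s in m.spans
                )
                if hit:
                    tags[k] = ("B-" if first else "I-") + m.label.value
                    first = False
        check_iob2(tags)
        out.append([Iob2Row(t.text, tag) for t, tag in zip(tokens, tags)])
    return out


def iob2_to_conll(sentences: list[list[Iob2Row]]) -> str:
    """CoNLL-style two-column TSV with blank lines between sentences."""
    blocks = [
        "\n".join(f"{row.token}\t{row.tag}" for row in sent) for sent in sentences
    ]
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# relation-instance export
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkedInstance:
    """One candidate (action, argument) pair in marker notation.

    ``text`` is the sentence with ``[E1]…[/E1]`` around the action and
    ``[E2]…[/E2]`` around the candidate argument.  The span/label metadata
    mirrors what a tagger already knew about the sentence; rule classifiers
    use it for nearest-action and intervening-mention tests.
    """

    text: str
    gold_label: str  # RelationLabel value or "NONE"
    head_id: str
    tail_id: str
    e1_label: EntityLabel
    e2_label: EntityLabel
    e1_surface: str
    e2_surface: str
    e1_span: TextSpan
    e2_span: TextSpan
    sentence_span: TextSpan
    sentence_text: str
    action_spans: tuple[TextSpan, ...] = ()
    entity_spans: tuple[TextSpan, ...] = ()


def _mark(sentence: str, base: int, e1: TextSpan, e2: TextSpan) -> str:
    inserts = sorted(
        [
            (e1.start - base, "[E1]"),
            (e1.end - base, "[/E1]"),
            (e2.start - base, "[E2]"),
            (e2.end - base, "[/E2]"),
        ],
        key=lambda kv: (kv[0], kv[1].startswith("[/")),
    )
    out = []
    last = 0
    for pos, marker in inserts:
        out.append(sentence[last:pos])
        out.append(marker)
        last = pos
    out.append(sentence[last:])
    return "".join(out)


def export_relation_instances(doc: AnnotatedDocument) -> list[MarkedInstance]:
    """All intra-sentence (REACTION_STEP, other-mention) candidate pairs.

    The gold label comes from a matching relation, else ``NONE``.  Pairs whose
    extents overlap (legal only across tracks) cannot be marked without
    nesting and are skipped.
    """
    gold = {(r.head, r.tail): r.label.value for r in doc.relations}
    sentences = split_sentences(doc.text)
    instances: list[MarkedInstance] = []
    mentions = sorted(doc.mentions, key=_mention_sort_key)
    for sent in sentences:
        inside = [m for m in mentions if sent.contains(m.extent)]
        actions = [m for m in inside if m.label == EntityLabel.REACTION_STEP]
        others = [m for m in inside if m.label != EntityLabel.REACTION_STEP]
        action_spans = tuple(m.extent for m in actions)
        entity_spans = tuple(
            m.extent for m in others if m.label == EntityLabel.ENTITY
        )
        sent_text = doc.text[sent.start : sent.end]
        for a in actions:
            for o in others:
                if a.extent.overlaps(o.extent):
                    continue
                instances.append(
                    MarkedInstance(
                        text=_mark(sent_text, sent.start, a.extent, o.extent),
                        gold_label=gold.get((a.id, o.id), "NONE"),
                        head_id=a.id,
                        tail_id=o.id,
                        e1_label=a.label,
                        e2_label=o.label,
                        e1_surface=a.surface,
                        e2_surface=o.surface,
                        e1_span=a.extent,
                        e2_span=o.extent,
                        sentence_span=sent,
                        sentence_text=sent_text,
                        action_spans=action_spans,
                        entity_spans=entity_spans,
                    )
                )
    return instances


def instances_to_tsv(instances: Iterable[MarkedInstance]) -> str:
    lines = [f"{inst.text}\t{inst.gold_label}" for inst in instances]
    return "\n".join(lines) + ("\n" if lines else "")
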