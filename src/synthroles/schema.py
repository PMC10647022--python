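"""Core annotation types for synthesis-procedure corpora.

A procedure document carries two layers of annotation:

* six entity labels — the action verb (``REACTION_STEP``), the substances and
  apparatus it manipulates (``ENTITY``), and four parameter labels
  (``TIME``, ``TEMPERATURE``, ``TEMP_TARGET``, ``MODIFIER``);
* four relation labels linking an action to its arguments — the numbered core
  roles ``ARG0``/``ARG1``/``ARG2`` (which must point at an ``ENTITY``) and the
  modifier role ``ARGM`` (which must point at a parameter).

Character offsets follow the brat standoff convention: 0-based, half-open,
over the raw document text with newlines preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence


class EntityLabel(str, Enum):
    """Closed set of span labels."""

    REACTION_STEP = "REACTION_STEP"
    ENTITY = "ENTITY"
    TIME = "TIME"
    TEMPERATURE = "TEMPERATURE"
    TEMP_TARGET = "TEMP_TARGET"
    MODIFIER = "MODIFIER"


#: Labels that denote reaction parameters (the legal targets of ARGM).
PARAMETER_LABELS = frozenset(
    {
        EntityLabel.TIME,
        EntityLabel.TEMPERATURE,
        EntityLabel.TEMP_TARGET,
        EntityLabel.MODIFIER,
    }
)


class RelationLabel(str, Enum):
    """Closed set of relation labels between an action and its argument."""

    ARG0 = "ARG0"
    ARG1 = "ARG1"
    ARG2 = "ARG2"
    ARGM = "ARGM"


#: Numbered core argument roles; their target must be an ENTITY mention.
CORE_ARGS = frozenset({RelationLabel.ARG0, RelationLabel.ARG1, RelationLabel.ARG2})


@dataclass(frozen=True, order=True)
class TextSpan:
    """Half-open character interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end


def expected_surface(text: str, spans: Sequence[TextSpan]) -> str:
    """Surface form covered by ``spans`` in ``text``.

    Fragments of a discontinuous mention are joined with a single space,
    matching how brat renders fragmented text-bound annotations.
    """
    return " ".join(text[s.start : s.end] for s in spans)


@dataclass
class Mention:
    """A labeled (possibly discontinuous) text span."""

    id: str
    label: EntityLabel
    spans: tuple[TextSpan, ...]
    surface: str

    def __post_init__(self) -> None:
        self.label = EntityLabel(self.label)
        self.spans = tuple(self.spans)
        if not self.spans:
            raise ValueError(f"mention {self.id} has no spans")

    @property
    def start(self) -> int:
        return self.spans[0].start

    @property
    def end(self) -> int:
        return self.spans[-1].end

    @property
    def extent(self) -> TextSpan:
        return TextSpan(self.start, self.end)


@dataclass
class Relation:
    """Typed link from a REACTION_STEP mention (head) to an argument (tail)."""

    id: str
    label: RelationLabel
    head: str
    tail: str

    def __post_init__(self) -> None:
        self.label = RelationLabel(self.label)


@dataclass
class AnnotatedDocument:
    """Procedure text plus its mention and relation annotations."""

    doc_id: str
    text: str
    mentions: list[Mention] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    split: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def mention_by_id(self, mention_id: str) -> Optional[Mention]:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        return None

    def mentions_with_label(self, label: EntityLabel) -> list[Mention]:
        return [m for m in self.mentions if m.label == label]

    def replace(self, **changes) -> "AnnotatedDocument":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    ids: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        """True when no hard constraint is violated (warnings allowed)."""
        return not self.errors

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}


def _check_mention(doc: AnnotatedDocument, m: Mention, issues: list[Issue]) -> bool:
    """Structural checks for one mention. Returns False on hard failure."""
    valid = True
    n = len(doc.text)
    prev_end = -1
    for s in m.spans:
        if s.end > n:
            issues.append(
                Issue("error", "span-out-of-bounds",
                      f"mention {m.id} span [{s.start},{s.end}) exceeds text length {n}",
                      (m.id,))
            )
            valid = False
        if s.start < prev_end:
            issues.append(
                Issue("error", "span-order",
                      f"mention {m.id} spans not sorted/disjoint", (m.id,))
            )
            valid = False
        prev_end = s.end
    if valid:
        want = expected_surface(doc.text, m.spans)
        if m.surface != want:
            issues.append(
                Issue("error", "surface-mismatch",
                      f"mention {m.id}: surface {m.surface!r} != text {want!r}",
                      (m.id,))
            )
            valid = False
    return valid


def validate_document(doc: AnnotatedDocument, registry=None) -> ValidationReport:
    """Validate structural and (optionally) roleset-level constraints.

    Hard errors: span bounds/order/surface problems, dangling relation
    endpoints, a non-action relation head, a relation label incompatible with
    its tail's entity label, duplicate (head, tail, label) triples, and —
    when a roleset ``registry`` is supplied — ARG0 used with any verb other
    than *contain*.

    Soft warnings (registry only): a relation label that the head's roleset
    does not define (e.g. ARG2 on a verb whose roleset has only ARG1), and an
    action surface that resolves to no roleset at all.  These mirror how such
    inconsistencies can be repaired downstream by consulting the roleset, so
    they never invalidate a document.

    Never raises on malformed content; every problem becomes an issue entry.
    """
    issues: list[Issue] = []
    by_id: dict[str, Mention] = {}
    for m in doc.mentions:
        _check_mention(doc, m, issues)
        if m.id in by_id:
            issues.append(
                Issue("error", "duplicate-mention-id",
                      f"mention id {m.id} used twice", (m.id,))
            )
        by_id[m.id] = m

    seen_triples: set[tuple[str, str, RelationLabel]] = set()
    for r in doc.relations:
        head = by_id.get(r.head)
        tail = by_id.get(r.tail)
        if head is None or tail is None:
            missing = r.head if head is None else r.tail
            issues.append(
                Issue("error", "unresolvable-reference",
                      f"relation {r.id} references unknown mention {missing}",
                      (r.id, missing))
            )
            continue
        if head.label != EntityLabel.REACTION_STEP:
            issues.append(
                Issue("error", "head-not-action",
                      f"relation {r.id} head {head.id} is {head.label.value}, "
                      "expected REACTION_STEP", (r.id, head.id))
            )
        if r.label in CORE_ARGS and tail.label != EntityLabel.ENTITY:
            issues.append(
                Issue("error", "label-incompatible",
                      f"relation {r.id}: {r.label.value} must point at ENTITY, "
                      f"got {tail.label.value}", (r.id, tail.id))
            )
        elif r.label == RelationLabel.ARGM and tail.label not in PARAMETER_LABELS:
            issues.append(
                Issue("error", "label-incompatible",
                      f"relation {r.id}: ARGM must point at a parameter, "
                      f"got {tail.label.value}", (r.id, tail.id))
            )
        triple = (r.head, r.tail, r.label)
        if triple in seen_triples:
            issues.append(
                Issue("error", "duplicate-relation",
                      f"relation {r.id} duplicates ({r.head}, {r.tail}, "
                      f"{r.label.value})", (r.id,))
            )
        seen_triples.add(triple)

        if registry is not None and head is not None:
            rs = registry.resolve(head.surface)
            if rs is None:
                issues.append(
                    Issue("warning", "unresolved-roleset",
                          f"action {head.id} surface {head.surface!r} resolves "
                          "to no roleset", (head.id,))
                )
            else:
                if r.label == RelationLabel.ARG0 and rs.lemma != "contain":
                    issues.append(
                        Issue("error", "arg0-requires-contain",
                              f"relation {r.id}: ARG0 is reserved for the "
                              f"container of 'contain', head is {rs.roleset_id}",
                              (r.id, head.id))
                    )
                elif r.label in CORE_ARGS and not rs.has_arg(r.label):
                    issues.append(
                        Issue("warning", "arg-not-in-roleset",
                              f"relation {r.id}: {r.label.value} is not a slot "
                              f"of {rs.roleset_id}", (r.id, head.id))
                    )

    if registry is not None:
        related_heads = {r.head for r in doc.relations}
        for m in doc.mentions:
            if m.label == EntityLabel.REACTION_STEP and m.id not in related_heads:
                if registry.resolve(m.surface) is None:
                    issues.append(
                        Issue("warning", "unresolved-roleset",
                              f"action {m.id} surface {m.surface!r} resolves "
                              "to no roleset", (m.id,))
                    )
    return ValidationReport(issues)
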