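"""Convert an annotated procedure into an ordered action sequence.

Each REACTION_STEP mention becomes exactly one step, in text-offset order, so
the sequence stays aligned with the source text: step *k* points back at the
verb's character span, and every argument surface is the exact text slice of
its mention.  Arguments are grouped by relation label; parameters are carried
verbatim (no unit parsing or chemistry inference).  Inconsistencies — a
relation label the head's roleset does not define, or a verb that resolves to
no roleset — are attached to the step as warnings, never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .rolesets import RolesetRegistry, default_registry, lemmatize
from .schema import (
    AnnotatedDocument,
    EntityLabel,
    Mention,
    RelationLabel,
    TextSpan,
)

SCHEMA_VERSION = "1"


@dataclass
class ActionStep:
    ordinal: int
    verb_surface: str
    lemma: str
    roleset_id: Optional[str]
    arg0: list[str] = field(default_factory=list)
    arg1: list[str] = field(default_factory=list)
    arg2: list[str] = field(default_factory=list)
    params: list[tuple[EntityLabel, str]] = field(default_factory=list)
    source_span: TextSpan = TextSpan(0, 1)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ActionSequence:
    doc_id: str
    steps: list[ActionStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


def _mention_order(m: Mention):
    return (m.start, m.end)


def build_sequence(
    doc: AnnotatedDocument, registry: Optional[RolesetRegistry] = None
) -> ActionSequence:
    """One step per REACTION_STEP mention, arguments grouped and ordered.

    Argument lists and parameters are ordered by their mentions' start
    offsets, so the result is invariant under permutation of the relation
    list.
    """
    registry = registry or default_registry()
    by_id = {m.id: m for m in doc.mentions}
    actions = sorted(
        (m for m in doc.mentions if m.label == EntityLabel.REACTION_STEP),
        key=_mention_order,
    )
    rels_by_head: dict[str, list] = {m.id: [] for m in actions}
    for r in doc.relations:
        if r.head in rels_by_head and r.tail in by_id:
            rels_by_head[r.head].append(r)

    steps = []
    for ordinal, action in enumerate(actions, 1):
        rs = registry.resolve(action.surface)
        warnings = []
        if rs is None:
            lemma = lemmatize(action.surface.split()[-1], registry.lemma_dict,
                              registry.lemmas | set(registry.lemma_dict.values()))
            warnings.append("unresolved-lemma")
        else:
            lemma = rs.lemma
        step = ActionStep(
            ordinal=ordinal,
            verb_surface=action.surface,
            lemma=lemma,
            roleset_id=rs.roleset_id if rs else None,
            source_span=action.extent,
            warnings=warnings,
        )
        for r in sorted(rels_by_head[action.id],
                        key=lambda r: _mention_order(by_id[r.tail])):
            tail = by_id[r.tail]
            if r.label == RelationLabel.ARGM:
                step.params.append((tail.label, tail.surface))
            else:
                if rs is not None and not rs.has_arg(r.label):
                    step.warnings.append(f"arg-not-in-roleset:{r.label.value}")
                getattr(step, r.label.value.lower()).append(tail.surface)
        steps.append(step)
    return ActionSequence(doc.doc_id, steps)


def render_text(seq: ActionSequence) -> str:
    """Numbered plain-text listing, one line per step.

    Format: ``N. <Lemma> [in <container>] <arg1, …> [→ <arg2, …>]
    [(<LABEL>: <param>, …)]``; steps carrying warnings get a ``[!]`` suffix.
    """
    lines = []
    for step in seq.steps:
        parts = [f"{step.ordinal}. {step.lemma.capitalize()}"]
        if step.arg0:
            parts.append("in " + ", ".join(step.arg0))
        if step.arg1:
            parts.append(", ".join(step.arg1))
        if step.arg2:
            parts.append("→ " + ", ".join(step.arg2))
        if step.params:
            parts.append(
                "(" + ", ".join(f"{lab.value}: {surf}" for lab, surf in step.params) + ")"
            )
        line = " ".join(parts)
        if step.warnings:
            line += " [!]"
        lines.append(line)
    return "\n".join(lines) + ("\n" if lines else "")


def render_json(seq: ActionSequence) -> str:
    """Loss-free, schema-versioned JSON serialization."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "doc_id": seq.doc_id,
        "steps": [
            {
                "ordinal": s.ordinal,
                "verb_surface": s.verb_surface,
                "lemma": s.lemma,
                "roleset_id": s.roleset_id,
                "arg0": s.arg0,
                "arg1": s.arg1,
                "arg2": s.arg2,
                "params": [[lab.value, surf] for lab, surf in s.params],
                "source_span": [s.source_span.start, s.source_span.end],
                "warnings": s.warnings,
            }
            for s in seq.steps
        ],
    }
    return json.dumps(payload, ensure_ascii=False, indent=2)


def parse_json(content: str) -> ActionSequence:
    """Inverse of :func:`render_json`."""
    payload = json.loads(content)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported sequence schema version {version!r}")
    steps = [
        ActionStep(
            ordinal=s["ordinal"],
            verb_surface=s["verb_surface"],
            lemma=s["lemma"],
            roleset_id=s["roleset_id"],
            arg0=list(s["arg0"]),
            arg1=list(s["arg1"]),
            arg2=list(s["arg2"]),
            params=[(EntityLabel(lab), surf) for lab, surf in s["params"]],
            source_span=TextSpan(*s["source_span"]),
            warnings=list(s["warnings"]),
        )
        for s in payload["steps"]
    ]
    return ActionSequence(payload["doc_id"], steps)
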