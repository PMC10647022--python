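"""NER → RE extraction pipeline with pluggable taggers and a rule baseline.

The pipeline mirrors how span-overlap between label families is handled by
running three independent tagging tracks per sentence — actions
(REACTION_STEP), entities (ENTITY) and parameters (TIME / TEMPERATURE /
TEMP_TARGET / MODIFIER) — and then classifying every intra-sentence
(action, other-mention) pair into a relation label or NONE.

Any component obeying the two contracts can be plugged in (e.g. a fine-tuned
transformer behind the same interface); the package ships a deterministic
rule/lexicon reference implementation whose pattern coverage is documented
below.  Mentions may overlap across tracks, never within one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

import yaml

from .brat import (
    MarkedInstance,
    Token,
    check_iob2,
    export_relation_instances,
    split_sentences,
    strip_note_refs,
    tokenize,
)
from .rolesets import RolesetRegistry, default_registry, lemmatize
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

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


class SequenceTagger(Protocol):
    """Contract: one sentence's tokens in, one IOB2 tag per token out."""

    track: str

    def tag(self, tokens: Sequence[Token]) -> list[str]: ...


class RelationClassifier(Protocol):
    """Contract: a marked instance in, a relation label or ``"NONE"`` out."""

    def classify(self, instance: MarkedInstance) -> str: ...


# ---------------------------------------------------------------------------
# configuration and lexicons
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("synthroles").joinpath("data", name)))


def _load_phrases(path: Union[str, Path]) -> tuple[str, ...]:
    phrases = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            phrases.append(line)
    return tuple(phrases)


@dataclass
class PipelineConfig:
    """Paths and toggles for a pipeline run.

    ``None`` lexicon paths fall back to the packaged files.  The
    ``attachment_window`` caps, in characters, how far a parameter may sit
    from its nearest action and still receive ARGM (``None`` = unlimited).
    """

    entity_lexicon: Optional[str] = None
    modifier_lexicon: Optional[str] = None
    temperature_lexicon: Optional[str] = None
    temp_target_lexicon: Optional[str] = None
    first_mention_filter: bool = True
    attachment_window: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for attr in ("entity_lexicon", "modifier_lexicon",
                     "temperature_lexicon", "temp_target_lexicon"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"lexicon file not found: {p}")
        return cfg


@dataclass(frozen=True)
class Lexicons:
    entities: tuple[str, ...]
    modifiers: tuple[str, ...]
    temperature_words: tuple[str, ...]
    temp_targets: tuple[str, ...]

    @classmethod
    def load(cls, config: Optional[PipelineConfig] = None) -> "Lexicons":
        config = config or PipelineConfig()
        return cls(
            entities=_load_phrases(config.entity_lexicon or _data_path("entities.txt")),
            modifiers=_load_phrases(config.modifier_lexicon or _data_path("modifiers.txt")),
            temperature_words=_load_phrases(
                config.temperature_lexicon or _data_path("temperature_words.txt")
            ),
            temp_targets=_load_phrases(
                config.temp_target_lexicon or _data_path("temp_targets.txt")
            ),
        )


def _phrase_index(phrases: Sequence[str]) -> dict[str, list[tuple[str, ...]]]:
    """First-token -> phrase token tuples, longest first."""
    index: dict[str, list[tuple[str, ...]]] = {}
    for phrase in phrases:
        toks = tuple(t.text.lower() for t in tokenize(phrase))
        index.setdefault(toks[0], []).append(toks)
    for v in index.values():
        v.sort(key=len, reverse=True)
    return index


def _match_phrase(
    tokens: Sequence[Token], i: int, index: dict[str, list[tuple[str, ...]]]
) -> int:
    """Length (in tokens) of the longest phrase starting at ``i``, else 0."""
    first = tokens[i].text.lower()
    for phrase in index.get(first, ()):  # longest first
        k = len(phrase)
        if i + k <= len(tokens) and all(
            tokens[i + j].text.lower() == phrase[j] for j in range(k)
        ):
            return k
    return 0


def _spans_to_iob2(
    tokens: Sequence[Token], spans: list[tuple[EntityLabel, int, int]]
) -> list[str]:
    """Token-index spans (label, first, last inclusive) to IOB2 tags."""
    tags = ["O"] * len(tokens)
    for label, first, last in spans:
        tags[first] = "B-" + label.value
        for k in range(first + 1, last + 1):
            tags[k] = "I-" + label.value
    return tags


# ---------------------------------------------------------------------------
# rule taggers
# ---------------------------------------------------------------------------

#: Auxiliary / linking tokens that license a verb reading for the next token.
_AUX_BEFORE = frozenset(
    {"was", "were", "is", "are", "be", "been", "being", "to", "then", "and"}
)

_NUM_RE = re.compile(r"^\d+(?:\.\d+)?(?:[-–]\d+(?:\.\d+)?)?$")
_NUM_UNIT_RE = re.compile(r"^\d+(?:\.\d+)?(?:[-–]\d+(?:\.\d+)?)?(h|hr|min)$")
_SIGNS = frozenset({"-", "−", "–", "+"})
_TIME_UNITS = frozenset(
    {"h", "hr", "hrs", "hour", "hours", "min", "mins", "minute", "minutes",
     "s", "sec", "seconds", "d", "day", "days"}
)


class RuleActionTagger:
    """Registry-driven REACTION_STEP tagger.

    A token is tagged when its lemma resolves to a roleset *and* it occurs in
    a verb context: sentence-initial (imperative), after an auxiliary/linking
    token (*was/were/is/are/to/then/and*), as a third-person present form
    (*contains*), or as a dictionary noun form followed by *of*
    (*addition of*).
    """

    track = "action"

    def __init__(self, registry: Optional[RolesetRegistry] = None):
        self.registry = registry or default_registry()
        self.lemma_dict = self.registry.lemma_dict
        self._known = self.registry.lemmas | set(self.lemma_dict.values())

    def tag(self, tokens: Sequence[Token]) -> list[str]:
        tags = ["O"] * len(tokens)
        for i, tok in enumerate(tokens):
            low = tok.text.lower()
            if not low or not low[0].isalpha():
                continue
            lemma = lemmatize(low, self.lemma_dict, self._known)
            if lemma not in self.registry:
                continue
            prev = tokens[i - 1].text.lower() if i > 0 else None
            nxt = tokens[i + 1].text.lower() if i + 1 < len(tokens) else None
            context = (
                i == 0
                or prev in _AUX_BEFORE
                or low in (lemma + "s", lemma + "es")
                or (low in self.lemma_dict and nxt == "of")
            )
            if context:
                tags[i] = "B-" + EntityLabel.REACTION_STEP.value
        return tags


class RuleEntityTagger:
    """Lexicon-driven ENTITY tagger.

    Matches the longest lexicon phrase at each position, then absorbs any
    directly following parenthesized amount or coreference group — one whose
    first token is numeric, e.g. ``(150 mL)`` or ``(1)`` — into the same span,
    implementing the one-span annotation policy.
    """

    track = "entity"

    def __init__(self, lexicons: Lexicons):
        self._index = _phrase_index(lexicons.entities)

    def tag(self, tokens: Sequence[Token]) -> list[str]:
        spans: list[tuple[EntityLabel, int, int]] = []
        i = 0
        while i < len(tokens):
            k = _match_phrase(tokens, i, self._index)
            if not k:
                i += 1
                continue
            last = i + k - 1
            j = last + 1
            while (
                j + 1 < len(tokens)
                and tokens[j].text == "("
                and _NUM_RE.match(tokens[j + 1].text)
            ):
                close = None
                for c in range(j + 1, min(j + 16, len(tokens))):
                    if tokens[c].text == ")":
                        close = c
                        break
                if close is None:
                    break
                last = close
                j = close + 1
            spans.append((EntityLabel.ENTITY, i, last))
            i = last + 1
        return _spans_to_iob2(tokens, spans)


class RuleParameterTagger:
    """Pattern + lexicon tagger for TIME / TEMPERATURE / TEMP_TARGET / MODIFIER.

    Matchers are tried in a fixed priority order at each position (temperature
    ranges, temperature-target phrases, temperature words and values, times,
    modifier phrases); the scan is greedy left to right, so spans within the
    track never overlap.
    """

    track = "parameter"

    def __init__(self, lexicons: Lexicons):
        self._temp_words = _phrase_index(lexicons.temperature_words)
        self._temp_targets = _phrase_index(lexicons.temp_targets)
        self._modifiers = _phrase_index(lexicons.modifiers)

    # each matcher returns the inclusive last token index of a match, or None
    def _match_numeric_temp(self, tokens, i) -> Optional[int]:
        j = i
        if tokens[j].text in _SIGNS and j + 1 < len(tokens):
            j += 1
        if (
            j + 1 < len(tokens)
            and _NUM_RE.match(tokens[j].text)
            and tokens[j + 1].text == "°C"
        ):
            return j + 1
        return None

    def _match_between_temp(self, tokens, i) -> Optional[int]:
        if tokens[i].text.lower() != "between":
            return None
        first = self._match_numeric_temp(tokens, i + 1) if i + 1 < len(tokens) else None
        if first is None or first + 1 >= len(tokens):
            return None
        if tokens[first + 1].text.lower() != "and":
            return None
        second = self._match_numeric_temp(tokens, first + 2)
        return second

    def _match_temp_word(self, tokens, i) -> Optional[int]:
        k = _match_phrase(tokens, i, self._temp_words)
        if not k:
            return None
        last = i + k - 1
        # one-span policy: absorb a parenthesized value, "room temperature (23 °C)"
        if (
            last + 4 <= len(tokens) - 1
            and tokens[last + 1].text == "("
            and _NUM_RE.match(tokens[last + 2].text)
            and tokens[last + 3].text == "°C"
            and tokens[last + 4].text == ")"
        ):
            last += 4
        return last

    def _match_time(self, tokens, i) -> Optional[int]:
        low = tokens[i].text.lower()
        if low == "overnight":
            return i
        if _NUM_UNIT_RE.match(low):
            return i
        if (
            _NUM_RE.match(tokens[i].text)
            and i + 1 < len(tokens)
            and tokens[i + 1].text.lower() in _TIME_UNITS
        ):
            return i + 1
        return None

    def tag(self, tokens: Sequence[Token]) -> list[str]:
        spans: list[tuple[EntityLabel, int, int]] = []
        i = 0
        while i < len(tokens):
            matched = None
            last = self._match_between_temp(tokens, i)
            if last is not None:
                matched = (EntityLabel.TEMPERATURE, i, last)
            if matched is None:
                k = _match_phrase(tokens, i, self._temp_targets)
                if k:
                    matched = (EntityLabel.TEMP_TARGET, i, i + k - 1)
            if matched is None:
                last = self._match_temp_word(tokens, i)
                if last is not None:
                    matched = (EntityLabel.TEMPERATURE, i, last)
            if matched is None:
                last = self._match_numeric_temp(tokens, i)
                if last is not None:
                    matched = (EntityLabel.TEMPERATURE, i, last)
            if matched is None:
                last = self._match_time(tokens, i)
                if last is not None:
                    matched = (EntityLabel.TIME, i, last)
            if matched is None:
                k = _match_phrase(tokens, i, self._modifiers)
                if k:
                    matched = (EntityLabel.MODIFIER, i, i + k - 1)
            if matched is None:
                i += 1
            else:
                spans.append(matched)
                i = matched[2] + 1
        return _spans_to_iob2(tokens, spans)


def default_taggers(
    config: Optional[PipelineConfig] = None,
    registry: Optional[RolesetRegistry] = None,
) -> dict[str, SequenceTagger]:
    lexicons = Lexicons.load(config)
    return {
        "action": RuleActionTagger(registry),
        "entity": RuleEntityTagger(lexicons),
        "parameter": RuleParameterTagger(lexicons),
    }


def rule_ner(
    tokens: Sequence[Token],
    track: str,
    lexicons: Optional[Lexicons] = None,
    registry: Optional[RolesetRegistry] = None,
) -> list[str]:
    """IOB2 tags for one sentence and track, via the rule baseline."""
    if track == "action":
        return RuleActionTagger(registry).tag(tokens)
    lexicons = lexicons or Lexicons.load()
    if track == "entity":
        return RuleEntityTagger(lexicons).tag(tokens)
    if track == "parameter":
        return RuleParameterTagger(lexicons).tag(tokens)
    raise ValueError(f"unknown track {track!r}")


# ---------------------------------------------------------------------------
# rule relation classifier
# ---------------------------------------------------------------------------

_PREPOSITIONS = frozenset({"to", "into", "in", "onto", "with"})


def _gap(a: TextSpan, b: TextSpan) -> int:
    if a.overlaps(b):
        return 0
    return b.start - a.end if a.end <= b.start else a.start - b.end


class RuleRelationClassifier:
    """Syntax-pattern classifier over marked instances.

    Parameters attach (ARGM) to the nearest action in the sentence.  For
    entities: a preceding surface subject with no action or other entity in
    between is ARG1 (ARG0 when the verb is *contain*); the object of
    *to/into/in/onto/with* after the action is ARG2 when the roleset defines
    that slot, else folded into ARG1; a bare direct object is ARG1.
    """

    def __init__(
        self,
        registry: Optional[RolesetRegistry] = None,
        attachment_window: Optional[int] = None,
    ):
        self.registry = registry or default_registry()
        self.attachment_window = attachment_window

    def classify(self, instance: MarkedInstance) -> str:
        e1, e2 = instance.e1_span, instance.e2_span
        if instance.e2_label in PARAMETER_LABELS:
            gap = _gap(e1, e2)
            if self.attachment_window is not None and gap > self.attachment_window:
                return "NONE"
            best = min(
                instance.action_spans or (e1,),
                key=lambda a: (_gap(a, e2), a.start),
            )
            return RelationLabel.ARGM.value if best == e1 else "NONE"

        rs = self.registry.resolve(instance.e1_surface)
        lemma = rs.lemma if rs is not None else None

        def blocked(lo: int, hi: int) -> bool:
            for s in instance.action_spans + instance.entity_spans:
                if s.start >= lo and s.end <= hi and s != e1 and s != e2:
                    return True
            return False

        base = instance.sentence_span.start
        if e2.end <= e1.start:
            if blocked(e2.end, e1.start):
                return "NONE"
            if lemma == "contain":
                return RelationLabel.ARG0.value
            return RelationLabel.ARG1.value
        if e1.end <= e2.start:
            if blocked(e1.end, e2.start):
                return "NONE"
            between = instance.sentence_text[e1.end - base : e2.start - base]
            words = re.findall(r"[A-Za-z]+", between)
            if words and words[-1].lower() in _PREPOSITIONS:
                if rs is not None and rs.has_arg(RelationLabel.ARG2):
                    return RelationLabel.ARG2.value
                return RelationLabel.ARG1.value
            if not words:
                return RelationLabel.ARG1.value
        return "NONE"


def rule_re(instance: MarkedInstance, registry: Optional[RolesetRegistry] = None) -> str:
    """Relation label (or ``"NONE"``) for one marked instance."""
    return RuleRelationClassifier(registry).classify(instance)


# ---------------------------------------------------------------------------
# first-mention policy
# ---------------------------------------------------------------------------

def _normalize_param(surface: str) -> str:
    return re.sub(r"\s+", "", surface).lower()


def apply_first_mention_filter(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Keep only the first occurrence of each repeated parameter value.

    Parameter mentions with the same label and whitespace/case-normalized
    surface within one procedure are reduced to the earliest; relations of
    dropped mentions are dropped with them.
    """
    seen: dict[tuple[EntityLabel, str], str] = {}
    keep: list[Mention] = []
    dropped: set[str] = set()
    for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
        if m.label in PARAMETER_LABELS:
            key = (m.label, _normalize_param(m.surface))
            if key in seen:
                dropped.add(m.id)
                continue
            seen[key] = m.id
        keep.append(m)
    rels = [r for r in doc.relations if r.tail not in dropped and r.head not in dropped]
    return doc.replace(mentions=keep, relations=rels)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _decode_iob2(tokens: Sequence[Token], tags: Sequence[str]) -> list[tuple[EntityLabel, TextSpan]]:
    spans = []
    start = end = None
    label = None
    for tok, tag in zip(tokens, tags):
        if tag.startswith("B-"):
            if start is not None:
                spans.append((label, TextSpan(start, end)))
            label = EntityLabel(tag[2:])
            start, end = tok.start, tok.end
        elif tag.startswith("I-"):
            end = tok.end
        else:
            if start is not None:
                spans.append((label, TextSpan(start, end)))
            start = end = label = None
    if start is not None:
        spans.append((label, TextSpan(start, end)))
    return spans


def run_pipeline(
    text: str,
    taggers: Optional[dict[str, SequenceTagger]] = None,
    re_model: Optional[RelationClassifier] = None,
    config: Optional[PipelineConfig] = None,
    doc_id: str = "doc",
    registry: Optional[RolesetRegistry] = None,
) -> AnnotatedDocument:
    """Full extraction: raw procedure text in, annotated document out.

    Stages: Note/Figure stripping → sentence splitting → the three tagging
    tracks → cross-track mention union (offsets mapped back to the original
    text) → pairwise relation classification → first-mention filtering.
    The returned document always validates structurally.
    """
    config = config or PipelineConfig()
    if taggers is None:
        taggers = default_taggers(config, registry)
    if re_model is None:
        re_model = RuleRelationClassifier(registry, config.attachment_window)

    cleaned, omap = strip_note_refs(text)
    sentences = split_sentences(cleaned)
    raw_spans: list[tuple[EntityLabel, TextSpan]] = []
    for sent in sentences:
        tokens = tokenize(cleaned[sent.start : sent.end], offset=sent.start)
        for track, tagger in taggers.items():
            tags = tagger.tag(tokens)
            if len(tags) != len(tokens):
                raise PipelineError(f"track {track!r} returned {len(tags)} tags "
                                    f"for {len(tokens)} tokens")
            try:
                check_iob2(tags)
            except ValueError as exc:
                raise PipelineError(f"track {track!r} emitted invalid IOB2: {exc}")
            raw_spans.extend(_decode_iob2(tokens, tags))

    mentions = []
    for label, span in sorted(raw_spans, key=lambda ls: (ls[1], ls[0].value)):
        orig = omap.map_span(span)
        mentions.append((label, orig))
    doc = AnnotatedDocument(doc_id, text)
    for i, (label, span) in enumerate(mentions, 1):
        doc.mentions.append(
            Mention(f"T{i}", label, (span,), expected_surface(text, [span]))
        )

    seen: set[tuple[str, str, RelationLabel]] = set()
    rid = 0
    for inst in export_relation_instances(doc):
        label = re_model.classify(inst)
        if label == "NONE":
            continue
        triple = (inst.head_id, inst.tail_id, RelationLabel(label))
        if triple in seen:
            continue
        seen.add(triple)
        rid += 1
        doc.relations.append(Relation(f"R{rid}", RelationLabel(label),
                                      inst.head_id, inst.tail_id))

    if config.first_mention_filter:
        doc = apply_first_mention_filter(doc)
    logger.info(
        "%s: %d sentences, %d mentions, %d relations",
        doc_id, len(sentences), len(doc.mentions), len(doc.relations),
    )
    return doc
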