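"""Seeded generator of annotated synthesis procedures, plus split/statistics.

The generator emulates the structure of real procedure corpora without any
claim to chemical validity: single-action passive sentences built from
per-roleset templates, entity slots filled from a small vocabulary of
substances/vessels with parenthesized amounts and coreference labels kept
inside the entity span (one-span policy), parameters annotated only at their
first mention, and a verb distribution that is heavily skewed toward *add*
and *stir* (default weights follow the per-verb occurrence totals observed
in real procedures).  Optional noise reproduces the quirks of the source
journal: parenthesized ``(Note n)``/``(Figure n)`` cross-references and
unannotated workup tails.

Everything is driven by one named PRNG stream, so a config is a complete
recipe: the same seed yields byte-identical corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .brat import split_sentences, write_standoff
from .rolesets import RolesetRegistry, default_registry
from .schema import (
    AnnotatedDocument,
    EntityLabel,
    Mention,
    Relation,
    RelationLabel,
    TextSpan,
)


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default verb weights: per-verb occurrence totals over a real corpus
#: (train+dev+test), i.e. the observed skewed distribution with add/stir
#: dominant.  `contain` is weighted 1, matching its single occurrence.
DEFAULT_VERB_WEIGHTS: dict[str, int] = {
    "add": 204, "stir": 143, "charge": 106, "cool": 65, "heat": 36,
    "remove": 17, "place": 12, "backfill": 11, "reflux": 8, "transfer": 4,
    "dissolve": 4, "wash": 2, "fill": 1, "wrap": 1, "hold": 2, "mix": 1,
    "open": 1, "activate": 1, "contain": 1, "keep": 2, "maintain": 2,
}


@dataclass
class NoiseFlags:
    note_refs: bool = False
    workup_tail: bool = False
    repeated_params: bool = False


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_procedures: int = 20
    sentences_per_procedure: tuple[int, int] = (3, 8)
    verb_weights: Optional[dict[str, float]] = None
    noise: NoiseFlags = field(default_factory=NoiseFlags)
    #: emit a deliberately roleset-inconsistent relation (ARG2 on `mix`)
    #: so validator warnings can be exercised; off by default.
    adversarial_roleset_args: bool = False


@dataclass(frozen=True)
class SplitRatio:
    train: int = 8
    dev: int = 1
    test: int = 1

    def __post_init__(self) -> None:
        if min(self.train, self.dev, self.test) <= 0:
            raise ValueError("split parts must be positive")
        if self.train < self.dev or self.train < self.test:
            raise ValueError("train part must be the largest")

    @property
    def total(self) -> int:
        return self.train + self.dev + self.test


# ---------------------------------------------------------------------------
# vocabulary (every entity phrase here must appear in data/entities.txt)
# ---------------------------------------------------------------------------

CHEMICALS = [
    "DMF", "THF", "anhydrous CH2Cl2", "dichloromethane", "toluene",
    "acetonitrile", "methanol", "benzaldehyde", "sodium hydride",
    "triethylamine", "potassium carbonate", "12-aminododecanolactam (1)",
    "aqueous NaHCO3", "diethyl ether",
]
SOLVENTS = ["toluene", "THF", "methanol", "acetonitrile", "dichloromethane", "DMF"]
AMOUNTS = [
    "(150 mL)", "(5 mL)", "(50 mL)", "(10 mL)", "(2.50 g, 12.0 mmol)",
    "(9.00 g, 45.6 mmol, 1.00 equiv)", "(1.2 equiv)", "(3.0 g)",
]
VESSELS = [
    "the flask", "the round-bottomed flask", "the reaction vessel",
    "the three-necked flask",
]
MIXTURES = ["the mixture", "the reaction mixture", "the solution", "the suspension"]
REMOVABLES = ["the ice bath", "the precipitate", "the solid"]
WASHABLES = ["the precipitate", "the solid"]
GASES = ["nitrogen gas", "argon gas"]
TIMES = [
    "2 h", "12 h", "30 min", "1.5 h", "16 h", "45 min", "14–15 h",
    "overnight", "5 min", "90 min", "3 days", "20 min",
]
POINT_TEMPS = [
    "0 °C", "−78 °C", "25 °C", "40 °C", "65 °C", "110 °C", "−40 °C",
    "50 °C", "room temperature", "room temperature (23 °C)",
]
RANGE_TEMPS = ["between 0 °C and 5 °C", "between 40 °C and 45 °C"]
TEMP_TARGETS = ["internal temperature", "bath temperature"]
DOSE_MODIFIERS = ["dropwise", "in one portion", "portionwise"]
ATMOSPHERE_MODIFIERS = ["under nitrogen", "under argon"]
STIR_MODIFIERS = ["with stirring", "with vigorous stirring"]
WORKUP_SENTENCES = [
    "The combined organic layers were washed with brine and dried over MgSO4.",
    "The crude residue was purified by flash column chromatography.",
    "The solvent was evaporated and the product was dried under high vacuum.",
]

ALL_ENTITY_PHRASES = sorted(
    {c.split(" (")[0] for c in CHEMICALS}
    | set(VESSELS) | set(MIXTURES) | set(REMOVABLES) | set(GASES)
    | {"aluminum foil"}
)


# ---------------------------------------------------------------------------
# document builder
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates text, mention spans and relations while templates run."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._len = 0
        self.mentions: list[tuple[EntityLabel, int, int]] = []
        self.relations: list[tuple[RelationLabel, int, int]] = []
        self._seen_params: set[tuple[EntityLabel, str]] = set()
        self._param_surfaces: dict[tuple[EntityLabel, str], str] = {}
        self._sentence_starts: list[int] = []

    def lit(self, s: str) -> None:
        self._parts.append(s)
        self._len += len(s)

    def begin_sentence(self) -> None:
        if self._len:
            self.lit(" ")
        self._sentence_starts.append(self._len)

    def _mention(self, label: EntityLabel, surface: str) -> int:
        start = self._len
        self.lit(surface)
        self.mentions.append((label, start, self._len))
        return len(self.mentions) - 1

    def entity(self, surface: str) -> int:
        return self._mention(EntityLabel.ENTITY, surface)

    def action(self, surface: str) -> int:
        return self._mention(EntityLabel.REACTION_STEP, surface)

    def rel(self, label: RelationLabel, head: int, tail: int) -> None:
        self.relations.append((label, head, tail))

    def target(self, surface: str) -> Optional[int]:
        """Parameter mention under the first-mention policy, no relation yet.

        Returns the mention index on first occurrence; repetitions are
        emitted as plain text and return None.
        """
        label = EntityLabel.TEMP_TARGET
        key = (label, "".join(surface.split()).lower())
        if key in self._seen_params:
            self.lit(surface)
            return None
        self._seen_params.add(key)
        self._param_surfaces.setdefault(key, surface)
        return self._mention(label, surface)

    def param(self, label: EntityLabel, surface: str, head: int) -> Optional[int]:
        """Parameter slot under the first-mention policy.

        The first occurrence of a (label, normalized surface) pair in the
        document becomes an annotated mention with an ARGM relation to
        ``head``; repetitions are emitted as plain text.
        """
        key = (label, "".join(surface.split()).lower())
        if key in self._seen_params:
            self.lit(surface)
            return None
        self._seen_params.add(key)
        self._param_surfaces.setdefault(key, surface)
        idx = self._mention(label, surface)
        self.rel(RelationLabel.ARGM, head, idx)
        return idx

    def finish(self, doc_id: str, meta: dict) -> AnnotatedDocument:
        chars = list("".join(self._parts))
        for pos in self._sentence_starts:
            chars[pos] = chars[pos].upper()
        text = "".join(chars)
        mentions = [
            Mention(f"T{i}", label, (TextSpan(s, e),), text[s:e])
            for i, (label, s, e) in enumerate(self.mentions, 1)
        ]
        relations = [
            Relation(f"R{i}", label, f"T{h + 1}", f"T{t + 1}")
            for i, (label, h, t) in enumerate(self.relations, 1)
        ]
        return AnnotatedDocument(doc_id, text, mentions, relations, meta=meta)


# ---------------------------------------------------------------------------
# sentence templates (one per roleset lemma; all passive-voice synthesis
# sentences inside the rule baseline's pattern coverage)
# ---------------------------------------------------------------------------

def _chem_phrase(rng: random.Random, pool: Sequence[str] = CHEMICALS) -> str:
    name = rng.choice(list(pool))
    if rng.random() < 0.7:
        return f"{name} {rng.choice(AMOUNTS)}"
    return name



def _emit_time(b, rng, act, prep: str) -> None:
    """Emit a time parameter; word expressions like *overnight* take no preposition."""
    t = rng.choice(TIMES)
    b.lit(" " if t == "overnight" else prep)
    b.param(EntityLabel.TIME, t, act)

def _t_add(b, rng):
    if rng.random() < 0.25:
        chem = b.entity(_chem_phrase(rng))
        b.lit(" was ")
        a1 = b.action("added")
        b.lit(" to ")
        dest = b.entity(rng.choice(VESSELS))
        b.lit(" and ")
        mix = b.entity("the mixture")
        b.lit(" was ")
        a2 = b.action("stirred")
        b.rel(RelationLabel.ARG1, a1, chem)
        b.rel(RelationLabel.ARG2, a1, dest)
        b.rel(RelationLabel.ARG1, a2, mix)
        _emit_time(b, rng, a2, " for ")
        return
    chem = b.entity(_chem_phrase(rng))
    b.lit(" was ")
    act = b.action("added")
    if rng.random() < 0.4:
        b.lit(" ")
        b.param(EntityLabel.MODIFIER, rng.choice(DOSE_MODIFIERS), act)
    b.lit(" to ")
    dest = b.entity(rng.choice(VESSELS + MIXTURES))
    b.rel(RelationLabel.ARG1, act, chem)
    b.rel(RelationLabel.ARG2, act, dest)
    roll = rng.random()
    if roll < 0.3:
        _emit_time(b, rng, act, " over ")
    elif roll < 0.55:
        b.lit(" at ")
        b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)
    elif roll < 0.7:
        b.lit(" ")
        b.param(EntityLabel.MODIFIER, rng.choice(STIR_MODIFIERS), act)


def _t_stir(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("stirred")
    b.rel(RelationLabel.ARG1, act, mix)
    if rng.random() < 0.35:
        b.lit(" ")
        b.param(EntityLabel.MODIFIER, rng.choice(ATMOSPHERE_MODIFIERS), act)
    if rng.random() < 0.6:
        b.lit(" at ")
        b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)
    _emit_time(b, rng, act, " for ")


def _t_charge(b, rng):
    vessel = b.entity(rng.choice(VESSELS))
    b.lit(" was ")
    act = b.action("charged")
    b.lit(" with ")
    chem = b.entity(_chem_phrase(rng))
    b.rel(RelationLabel.ARG1, act, vessel)
    b.rel(RelationLabel.ARG2, act, chem)
    if rng.random() < 0.3:
        b.lit(" ")
        b.param(EntityLabel.MODIFIER, rng.choice(ATMOSPHERE_MODIFIERS), act)


def _t_cool(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("cooled")
    b.rel(RelationLabel.ARG1, act, mix)
    if rng.random() < 0.25:
        b.lit(" in an ")
        b.param(EntityLabel.TEMPERATURE, "ice/water", act)
        b.lit(" bath")
        return
    b.lit(" to ")
    temp = rng.choice(POINT_TEMPS + RANGE_TEMPS)
    b.param(EntityLabel.TEMPERATURE, temp, act)
    if rng.random() < 0.3:
        _emit_time(b, rng, act, " over ")


def _t_heat(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("heated")
    b.rel(RelationLabel.ARG1, act, mix)
    b.lit(" at ")
    b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)
    _emit_time(b, rng, act, " for ")


def _t_remove(b, rng):
    thing = b.entity(rng.choice(REMOVABLES))
    b.lit(" was ")
    act = b.action("removed")
    b.rel(RelationLabel.ARG1, act, thing)


def _t_place(b, rng):
    chem = b.entity(_chem_phrase(rng))
    b.lit(" was ")
    act = b.action("placed")
    b.lit(" in ")
    vessel = b.entity(rng.choice(VESSELS))
    b.rel(RelationLabel.ARG1, act, chem)
    b.rel(RelationLabel.ARG2, act, vessel)


def _t_backfill(b, rng):
    vessel = b.entity(rng.choice(VESSELS))
    b.lit(" was ")
    act = b.action("backfilled")
    b.lit(" with ")
    gas = b.entity(rng.choice(GASES))
    b.rel(RelationLabel.ARG1, act, vessel)
    b.rel(RelationLabel.ARG2, act, gas)


def _t_reflux(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("refluxed")
    b.rel(RelationLabel.ARG1, act, mix)
    _emit_time(b, rng, act, " for ")


def _t_transfer(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("transferred")
    b.lit(" to ")
    vessel = b.entity(rng.choice(VESSELS))
    b.rel(RelationLabel.ARG1, act, mix)
    b.rel(RelationLabel.ARG2, act, vessel)


def _t_dissolve(b, rng):
    pool = [c for c in CHEMICALS if c not in SOLVENTS]
    chem = b.entity(_chem_phrase(rng, pool))
    b.lit(" was ")
    act = b.action("dissolved")
    b.lit(" in ")
    solvent = b.entity(_chem_phrase(rng, SOLVENTS))
    b.rel(RelationLabel.ARG1, act, chem)
    b.rel(RelationLabel.ARG2, act, solvent)


def _t_wash(b, rng):
    thing = b.entity(rng.choice(WASHABLES))
    b.lit(" was ")
    act = b.action("washed")
    b.lit(" with ")
    solvent = b.entity(_chem_phrase(rng, SOLVENTS))
    b.rel(RelationLabel.ARG1, act, thing)
    b.rel(RelationLabel.ARG2, act, solvent)


def _t_fill(b, rng):
    vessel = b.entity(rng.choice(VESSELS))
    b.lit(" was ")
    act = b.action("filled")
    b.lit(" with ")
    chem = b.entity(_chem_phrase(rng, SOLVENTS))
    b.rel(RelationLabel.ARG1, act, vessel)
    b.rel(RelationLabel.ARG2, act, chem)


def _t_wrap(b, rng):
    vessel = b.entity(rng.choice(VESSELS))
    b.lit(" was ")
    act = b.action("wrapped")
    b.lit(" with ")
    foil = b.entity("aluminum foil")
    b.rel(RelationLabel.ARG1, act, vessel)
    b.rel(RelationLabel.ARG2, act, foil)


def _t_hold(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("held")
    b.rel(RelationLabel.ARG1, act, mix)
    b.lit(" at ")
    b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS + RANGE_TEMPS), act)
    if rng.random() < 0.5:
        _emit_time(b, rng, act, " for ")


def _t_mix(b, rng, adversarial=False):
    pool = list(CHEMICALS)
    first = rng.choice(pool)
    pool.remove(first)
    chem1 = b.entity(first if rng.random() < 0.5 else f"{first} {rng.choice(AMOUNTS)}")
    b.lit(" was ")
    act = b.action("mixed")
    b.lit(" with ")
    chem2 = b.entity(_chem_phrase(rng, pool))
    b.rel(RelationLabel.ARG1, act, chem1)
    # `mix` defines only ARG1 (ingredient); the adversarial switch emits the
    # roleset-inconsistent ARG2 instead so validators can be exercised.
    b.rel(RelationLabel.ARG2 if adversarial else RelationLabel.ARG1, act, chem2)


def _t_open(b, rng):
    vessel = b.entity(rng.choice(VESSELS))
    b.lit(" was ")
    act = b.action("opened")
    b.rel(RelationLabel.ARG1, act, vessel)


def _t_activate(b, rng):
    chem = b.entity(_chem_phrase(rng))
    b.lit(" was ")
    act = b.action("activated")
    b.rel(RelationLabel.ARG1, act, chem)
    b.lit(" at ")
    b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)


def _t_contain(b, rng):
    vessel = b.entity(rng.choice(VESSELS))
    b.lit(" ")
    act = b.action("contains")
    b.lit(" ")
    chem = b.entity(_chem_phrase(rng))
    b.rel(RelationLabel.ARG0, act, vessel)
    b.rel(RelationLabel.ARG1, act, chem)


def _t_keep(b, rng):
    mix = b.entity(rng.choice(MIXTURES))
    b.lit(" was ")
    act = b.action("kept")
    b.rel(RelationLabel.ARG1, act, mix)
    b.lit(" at ")
    b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)
    if rng.random() < 0.5:
        b.lit(" ")
        b.param(EntityLabel.TIME, "overnight", act)


def _t_maintain(b, rng):
    # "The internal temperature was maintained at 0 °C."
    b.lit("the ")
    idx = b.target(rng.choice(TEMP_TARGETS))
    b.lit(" was ")
    act = b.action("maintained")
    b.lit(" at ")
    b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)
    if idx is not None:
        b.rel(RelationLabel.ARGM, act, idx)


TEMPLATES = {
    "add": _t_add, "stir": _t_stir, "charge": _t_charge, "cool": _t_cool,
    "heat": _t_heat, "remove": _t_remove, "place": _t_place,
    "backfill": _t_backfill, "reflux": _t_reflux, "transfer": _t_transfer,
    "dissolve": _t_dissolve, "wash": _t_wash, "fill": _t_fill,
    "wrap": _t_wrap, "hold": _t_hold, "mix": _t_mix, "open": _t_open,
    "activate": _t_activate, "contain": _t_contain, "keep": _t_keep,
    "maintain": _t_maintain,
}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(
    config: Optional[GeneratorConfig] = None,
    registry: Optional[RolesetRegistry] = None,
) -> list[AnnotatedDocument]:
    """Generate ``config.n_procedures`` annotated procedure documents."""
    config = config or GeneratorConfig()
    registry = registry or default_registry()
    weights = dict(config.verb_weights or DEFAULT_VERB_WEIGHTS)
    for lemma, w in weights.items():
        if lemma not in registry:
            raise GeneratorError(f"verb weight for unknown lemma {lemma!r}")
        if lemma not in TEMPLATES:
            raise GeneratorError(f"no sentence template for lemma {lemma!r}")
        if w <= 0:
            raise GeneratorError(f"weight for {lemma!r} must be positive")
    lemmas = sorted(weights)
    wvals = [weights[l] for l in lemmas]
    rng = random.Random(config.seed)
    lo, hi = config.sentences_per_procedure
    docs = []
    for i in range(config.n_procedures):
        b = _Builder()
        note_no = 1
        for _ in range(rng.randint(lo, hi)):
            lemma = rng.choices(lemmas, weights=wvals, k=1)[0]
            b.begin_sentence()
            if lemma == "mix":
                _t_mix(b, rng, adversarial=config.adversarial_roleset_args)
            else:
                TEMPLATES[lemma](b, rng)
            if config.noise.note_refs and rng.random() < 0.35:
                kind = "Note" if rng.random() < 0.7 else "Figure"
                b.lit(f" ({kind} {note_no})")
                note_no += 1
            b.lit(".")
        if config.noise.repeated_params:
            reused = sorted(
                surf for (lab, _), surf in b._param_surfaces.items()
                if lab == EntityLabel.TIME
            )
            if reused:
                # deliberate repetition of an already-annotated time value;
                # per the first-mention policy it stays unannotated
                b.begin_sentence()
                b.lit("after ")
                b.lit(rng.choice(reused))
                b.lit(", ")
                mix = b.entity(rng.choice(MIXTURES))
                b.lit(" was ")
                act = b.action("stirred")
                b.rel(RelationLabel.ARG1, act, mix)
                b.lit(" at ")
                b.param(EntityLabel.TEMPERATURE, rng.choice(POINT_TEMPS), act)
                b.lit(".")
        if config.noise.workup_tail:
            for sent in rng.sample(WORKUP_SENTENCES, rng.randint(1, 2)):
                b.lit(" " + sent)
        doc = b.finish(
            f"proc{i:04d}",
            meta={"seed": config.seed, "index": i, "generator": "synthroles"},
        )
        docs.append(doc)
    return docs


def write_corpus(
    docs: Iterable[AnnotatedDocument], outdir: Union[str, Path]
) -> None:
    """Write ``<outdir>/<split>/<doc_id>.{txt,ann}`` trees (split or 'all')."""
    outdir = Path(outdir)
    for doc in docs:
        write_standoff(doc, outdir / (doc.split or "all"))


# ---------------------------------------------------------------------------
# splitting and statistics
# ---------------------------------------------------------------------------

def split_sizes(n: int, ratio: Optional[SplitRatio] = None) -> tuple[int, int, int]:
    """(train, dev, test) sizes: dev/test get floor(n·part/total), train the rest."""
    ratio = ratio or SplitRatio()
    dev = n * ratio.dev // ratio.total
    test = n * ratio.test // ratio.total
    return n - dev - test, dev, test


def split_corpus(
    docs: Sequence[AnnotatedDocument],
    ratio: Optional[SplitRatio] = None,
    seed: int = 0,
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Procedure-level split by seeded shuffle then contiguous slicing."""
    if len(docs) < 3:
        raise GeneratorError("need at least 3 documents to split")
    n_train, n_dev, n_test = split_sizes(len(docs), ratio)
    order = list(docs)
    random.Random(seed).shuffle(order)
    train = [d.replace(split="train") for d in order[:n_train]]
    dev = [d.replace(split="dev") for d in order[n_train : n_train + n_dev]]
    test = [d.replace(split="test") for d in order[n_train + n_dev :]]
    return train, dev, test


def with_total_row(df: pd.DataFrame) -> pd.DataFrame:
    """Append a 'total' row holding the column sums."""
    out = df.copy()
    out.loc["total"] = df.sum(axis=0)
    return out


@dataclass
class CorpusStats:
    procedures: pd.DataFrame
    ner: pd.DataFrame
    re: pd.DataFrame


_NER_ORDER = [l.value for l in (
    EntityLabel.REACTION_STEP, EntityLabel.ENTITY, EntityLabel.TEMPERATURE,
    EntityLabel.TEMP_TARGET, EntityLabel.TIME, EntityLabel.MODIFIER,
)]
_RE_ORDER = [l.value for l in (
    RelationLabel.ARG1, RelationLabel.ARG2, RelationLabel.ARGM, RelationLabel.ARG0,
)]


def corpus_stats(docs: Iterable[AnnotatedDocument]) -> CorpusStats:
    """Per-split procedure/sentence counts and NER/RE label counts.

    Documents without split metadata fall into an 'all' column.  Each label
    table carries a 'total' row equal to its column sums.
    """
    splits: dict[str, list[AnnotatedDocument]] = {}
    for doc in docs:
        splits.setdefault(doc.split or "all", []).append(doc)
    if not splits:
        splits = {"all": []}
    order = [s for s in ("train", "dev", "test", "all") if s in splits]

    proc_rows = {}
    ner = pd.DataFrame(0, index=_NER_ORDER, columns=order)
    re_df = pd.DataFrame(0, index=_RE_ORDER, columns=order)
    for split in order:
        ds = splits[split]
        proc_rows[split] = {
            "procedures": len(ds),
            "sentences": sum(len(split_sentences(d.text)) for d in ds),
        }
        for d in ds:
            for m in d.mentions:
                ner.loc[m.label.value, split] += 1
            for r in d.relations:
                re_df.loc[r.label.value, split] += 1
    procedures = pd.DataFrame.from_dict(proc_rows, orient="index")
    if not procedures.empty:
        procedures = with_total_row(procedures)
    return CorpusStats(procedures, with_total_row(ner), with_total_row(re_df))
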