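"""Roleset inventory: verb senses with numbered argument slots.

A *roleset* pairs a verb lemma with described argument slots, PropBank-style,
capped at ARG2 (two numbered slots were enough to cover synthesis actions;
slots are renumbered downward so rare high-numbered labels never occur, and
every lemma carries exactly one sense, suffixed ``.01``).  Each roleset also
records where it came from:

* ``A`` — taken from PropBank as-is (possibly reworded),
* ``B`` — PropBank roleset whose argument definitions were altered
  (e.g. *mix*, whose two "ingredient" slots collapse into one ARG1),
* ``C`` — new roleset for a verb PropBank already lists,
* ``D`` — new roleset for a verb absent from PropBank.

The registry ships as a plain TSV so chemists can extend it without touching
code; registry size is a data property, not a constant.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

from .schema import RelationLabel

logger = logging.getLogger(__name__)

ORIGIN_TYPES = ("A", "B", "C", "D")

_WORD_RE = re.compile(r"[A-Za-z][A-Za-z-]*")


class RegistryError(ValueError):
    """Raised when a registry or dictionary file violates its invariants."""


@dataclass(frozen=True)
class ArgSlot:
    """One numbered argument slot with its free-text description."""

    index: int
    description: str

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 2:
            raise ValueError(f"argument index {self.index} exceeds ARG2 cap")


@dataclass(frozen=True)
class Roleset:
    roleset_id: str
    lemma: str
    slots: tuple[ArgSlot, ...]
    origin_type: str

    def __post_init__(self) -> None:
        if not self.roleset_id.endswith(".01"):
            raise ValueError(f"sense suffix must be .01: {self.roleset_id}")
        if self.origin_type not in ORIGIN_TYPES:
            raise ValueError(f"unknown origin type {self.origin_type!r}")
        indices = [s.index for s in self.slots]
        if len(indices) != len(set(indices)):
            raise ValueError(f"duplicate slot indices in {self.roleset_id}")

    def has_arg(self, label: RelationLabel) -> bool:
        """True iff a numbered slot matching ``label`` exists.

        ARGM is not slot-governed (any parameter may attach to any action),
        so passing it is a contract violation.
        """
        label = RelationLabel(label)
        if label == RelationLabel.ARGM:
            raise ValueError("ARGM is not a numbered slot; it is always allowed")
        index = int(label.value[3])
        return any(s.index == index for s in self.slots)


class RolesetRegistry(Mapping[str, Roleset]):
    """Mapping lemma -> Roleset, with surface-form resolution attached."""

    def __init__(self, rolesets: Iterable[Roleset], lemma_dict: Optional[dict[str, str]] = None):
        self._by_lemma: dict[str, Roleset] = {}
        for rs in rolesets:
            if rs.lemma in self._by_lemma:
                raise RegistryError(f"duplicate roleset for lemma {rs.lemma!r}")
            self._by_lemma[rs.lemma] = rs
        self.lemma_dict = dict(lemma_dict or {})
        for rs in self._by_lemma.values():
            if not rs.has_arg(RelationLabel.ARG1):
                logger.warning("roleset %s defines no ARG1 slot", rs.roleset_id)

    def __getitem__(self, lemma: str) -> Roleset:
        return self._by_lemma[lemma]

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_lemma)

    def __len__(self) -> int:
        return len(self._by_lemma)

    def get(self, lemma: str, default=None):
        return self._by_lemma.get(lemma, default)

    @property
    def lemmas(self) -> set[str]:
        return set(self._by_lemma)

    def resolve(self, mention_surface: str) -> Optional[Roleset]:
        return resolve(mention_surface, self, self.lemma_dict)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("synthroles").joinpath("data", name)))


def load_lemma_dictionary(path: Union[str, Path, None] = None) -> dict[str, str]:
    """Load the surface->lemma dictionary (noun forms, irregular inflections)."""
    path = _data_path("lemma_dict.tsv") if path is None else Path(path)
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise RegistryError(f"{path}:{lineno}: expected surface<TAB>lemma")
        entries[parts[0].lower()] = parts[1].lower()
    return entries


def load_registry(
    path: Union[str, Path, None] = None,
    lemma_dict: Union[dict[str, str], None] = None,
) -> RolesetRegistry:
    """Load the roleset registry from a TSV file.

    Row format: ``lemma<TAB>sense<TAB>origin_type<TAB>arg0<TAB>arg1<TAB>arg2``
    with an empty description meaning the slot is absent.  ``#`` lines are
    comments.  Duplicate lemmas and malformed rows raise :class:`RegistryError`
    (at most one roleset per lemma is a corpus-level invariant).
    """
    path = _data_path("rolesets.tsv") if path is None else Path(path)
    rolesets: list[Roleset] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if not 3 <= len(parts) <= 6:
            raise RegistryError(
                f"{path}:{lineno}: expected 3-6 tab-separated fields"
            )
        parts += [""] * (6 - len(parts))  # trailing empty slots may be omitted
        lemma, sense, origin, *descs = parts
        lemma = lemma.strip().lower()
        if sense.strip() != "01":
            raise RegistryError(f"{path}:{lineno}: sense must be 01, got {sense!r}")
        slots = tuple(
            ArgSlot(i, d.strip()) for i, d in enumerate(descs) if d.strip()
        )
        try:
            rolesets.append(Roleset(f"{lemma}.01", lemma, slots, origin.strip()))
        except ValueError as exc:
            raise RegistryError(f"{path}:{lineno}: {exc}") from exc
    if lemma_dict is None:
        lemma_dict = load_lemma_dictionary()
    return RolesetRegistry(rolesets, lemma_dict)


_SUFFIXES = ("ing", "ed", "es", "s")


def lemmatize(
    token: str,
    lemma_dict: Optional[dict[str, str]] = None,
    known_lemmas: Optional[set[str]] = None,
) -> str:
    """Lowercase verb lemma of ``token``.

    The custom dictionary (noun forms such as *addition*, irregulars such as
    *held*) is consulted first, then inflectional suffixes are stripped and
    the candidate bases (as-is, with restored final *e*, with an undoubled
    final consonant) are confirmed against the known lemma set.  Unknown
    tokens come back as their lowercased selves, which makes the function
    idempotent.
    """
    if lemma_dict is None:
        lemma_dict = _default_lemma_dict()
    if known_lemmas is None:
        known_lemmas = _default_known_lemmas()
    low = token.lower()
    if low in lemma_dict:
        return lemma_dict[low]
    if low in known_lemmas:
        return low
    for suffix in _SUFFIXES:
        if not low.endswith(suffix):
            continue
        base = low[: -len(suffix)]
        if len(base) < 2:
            continue
        candidates = [base, base + "e"]
        if len(base) > 2 and base[-1] == base[-2]:
            candidates.append(base[:-1])
        for cand in candidates:
            if cand in lemma_dict:
                return lemma_dict[cand]
            if cand in known_lemmas:
                return cand
    return low


def resolve(
    mention_surface: str,
    registry: RolesetRegistry,
    lemma_dict: Optional[dict[str, str]] = None,
) -> Optional[Roleset]:
    """Resolve an action mention surface (e.g. ``"was added"``) to a roleset.

    Each word token of the surface is lemmatized in turn; the first lemma
    present in the registry wins.  Returns None when nothing resolves.
    """
    if lemma_dict is None:
        lemma_dict = registry.lemma_dict
    known = registry.lemmas | set(lemma_dict.values())
    for match in _WORD_RE.finditer(mention_surface):
        lemma = lemmatize(match.group(0), lemma_dict, known)
        rs = registry.get(lemma)
        if rs is not None:
            return rs
    return None


def has_arg(rs: Roleset, label: RelationLabel) -> bool:
    return rs.has_arg(label)


def type_distribution(registry: RolesetRegistry) -> dict[str, int]:
    """Counts of rolesets per origin type; keys always cover A-D."""
    counts = {t: 0 for t in ORIGIN_TYPES}
    for rs in registry.values():
        counts[rs.origin_type] += 1
    return counts


def type_shares(counts: Union[RolesetRegistry, Mapping[str, int]]) -> dict[str, int]:
    """Origin-type shares as integer percentages (rounded to nearest)."""
    if isinstance(counts, RolesetRegistry):
        counts = type_distribution(counts)
    total = sum(counts.get(t, 0) for t in ORIGIN_TYPES)
    if total == 0:
        return {t: 0 for t in ORIGIN_TYPES}
    return {t: round(100 * counts.get(t, 0) / total) for t in ORIGIN_TYPES}


_DEFAULTS: dict = {}


def _default_lemma_dict() -> dict[str, str]:
    if "dict" not in _DEFAULTS:
        _DEFAULTS["dict"] = load_lemma_dictionary()
    return _DEFAULTS["dict"]


def _default_known_lemmas() -> set[str]:
    if "lemmas" not in _DEFAULTS:
        reg = default_registry()
        _DEFAULTS["lemmas"] = reg.lemmas | set(reg.lemma_dict.values())
    return _DEFAULTS["lemmas"]


def default_registry() -> RolesetRegistry:
    """The packaged registry (loaded once, cached)."""
    if "registry" not in _DEFAULTS:
        _DEFAULTS["registry"] = load_registry()
    return _DEFAULTS["registry"]
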