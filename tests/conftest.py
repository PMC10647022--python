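import pytest

from synthroles.rolesets import default_registry
from synthroles.schema import (
    AnnotatedDocument,
    EntityLabel,
    Mention,
    Relation,
    RelationLabel,
    TextSpan,
)
from synthroles.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def corpus20():
    """Noise-free synthetic corpus, seed 7, 20 procedures."""
    return generate(GeneratorConfig(seed=7, n_procedures=20))


def make_doc(text, mention_specs, relation_specs=(), doc_id="doc"):
    """Build a document from (label, surface[, occurrence]) mention specs.

    Spans are located by searching for the surface in the text, so tests can
    state annotations without hand-counting offsets.
    """
    mentions = []
    for i, spec in enumerate(mention_specs, 1):
        label, surface, *rest = spec
        occurrence = rest[0] if rest else 0
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(surface, start + 1)
        mentions.append(
            Mention(f"T{i}", EntityLabel(label),
                    (TextSpan(start, start + len(surface)),), surface)
        )
    relations = [
        Relation(f"R{j}", RelationLabel(label), head, tail)
        for j, (label, head, tail) in enumerate(relation_specs, 1)
    ]
    return AnnotatedDocument(doc_id, text, mentions, relations)


@pytest.fixture
def two_step_doc():
    """Gold-annotated two-action sentence used across modules."""
    text = ("A (1 g) was added to B (5 mL) and the mixture was stirred "
            "at 0 °C for 2 h.")
    return make_doc(
        text,
        [
            ("ENTITY", "A (1 g)"),
            ("REACTION_STEP", "added"),
            ("ENTITY", "B (5 mL)"),
            ("ENTITY", "the mixture"),
            ("REACTION_STEP", "stirred"),
            ("TEMPERATURE", "0 °C"),
            ("TIME", "2 h"),
        ],
        [
            ("ARG1", "T2", "T1"),
            ("ARG2", "T2", "T3"),
            ("ARG1", "T5", "T4"),
            ("ARGM", "T5", "T6"),
            ("ARGM", "T5", "T7"),
        ],
    )
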