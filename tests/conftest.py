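import pytest

from semcat.annotation_io import AnnotatedSpan, Corpus, Document
from semcat.lexicon import LexicalResource


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two documents, four spans, two categories; offsets checked by hand."""
    d1 = Document("d1", "Fibrin binds plasminogen today")
    d2 = Document("d2", "aspirin and heparin were given")
    spans = [
        AnnotatedSpan("d1", 0, 6, "PROTEIN", "Fibrin"),
        AnnotatedSpan("d1", 13, 24, "PROTEIN", "plasminogen"),
        AnnotatedSpan("d2", 0, 7, "CHEMICAL", "aspirin"),
        AnnotatedSpan("d2", 12, 19, "CHEMICAL", "heparin"),
    ]
    return Corpus(documents={"d1": d1, "d2": d2}, spans=spans,
                  categories=("PROTEIN", "CHEMICAL"))


@pytest.fixture
def protein_resource() -> LexicalResource:
    return LexicalResource(
        name="PROTEIN",
        entries=frozenset({"fibrin", "plasminogen", "thrombin", "albumin"}),
    )


@pytest.fixture
def chemical_resource() -> LexicalResource:
    return LexicalResource(
        name="CHEMICAL",
        entries=frozenset({"aspirin", "heparin", "warfarin"}),
    )
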