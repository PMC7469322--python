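import pytest

from sipnet import (
    Document,
    InteractionTerms,
    Lexicon,
    LexiconEntry,
    split_sentences,
)


def make_document(doc_id: str, abstract: str, title: str = "t") -> Document:
    doc = Document(doc_id=doc_id, title=title, abstract=abstract,
                   sentences=split_sentences(abstract))
    doc.validate()
    return doc


@pytest.fixture
def gene_lexicon() -> Lexicon:
    return Lexicon([
        LexiconEntry("TP53", ("p53",), "gene", "Homo sapiens"),
        LexiconEntry("BAX", (), "gene", "Homo sapiens"),
        LexiconEntry("KRAS", (), "gene", "Homo sapiens"),
        LexiconEntry("colorectal cancer", ("CRC",), "disease", "Homo sapiens"),
    ])


@pytest.fixture
def terms() -> InteractionTerms:
    return InteractionTerms(("activates", "activation", "inhibits", "binds"))
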