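import pytest

from renet_ft.corpus_io import (
    Document,
    EntityClass,
    EntityMention,
    Passage,
    SectionType,
)
from renet_ft.synthetic_corpus import GeneratorConfig, generate_corpus


def build_doc(doc_id, passage_specs, mention_specs=()):
    """Construct a document from (section, text) passages and global-span mentions."""
    passages = []
    offset = 0
    sec_counter = {}
    for sec, text in passage_specs:
        idx = sec_counter.get(sec, 0)
        sec_counter[sec] = idx + 1
        passages.append(Passage(sec, idx, offset, text))
        offset += len(text)
    doc = Document(doc_id=doc_id, passages=passages)
    text = doc.text
    mentions = []
    for start, end, cls, cid in mention_specs:
        mentions.append(
            EntityMention(start, end, text[start:end], EntityClass(cls), cid)
        )
    doc.mentions = mentions
    return doc


@pytest.fixture(scope="session")
def small_corpus():
    """20 deterministic synthetic documents with complete truth labels."""
    return generate_corpus(GeneratorConfig(n_docs=20, seed=42))


@pytest.fixture(scope="session")
def midsize_corpus():
    """50 synthetic documents for oracle-equivalence checks."""
    return generate_corpus(GeneratorConfig(n_docs=50, noise_paragraph_rate=0.8, seed=7))


@pytest.fixture()
def simple_doc():
    """One sentence, one gene and one disease mention."""
    return build_doc(
        "D1",
        [(SectionType.TITLE, "BRCA1 causes cancer . ")],
        [(0, 5, "Gene", "GENE:1"), (13, 19, "Disease", "MESH:D1")],
    )
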