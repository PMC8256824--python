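"""Synthetic annotated corpora with planted gene-disease relations.

Every downstream stage (section filtering, encoding, training, ensembling,
silver-set mining, evaluation) is exercised against corpora generated here,
so the generator produces complete ground truth: for each document, every
(gene, disease) concept-ID pair receives a label — 1.0 if the document
contains at least one assertive trigger sentence for the pair, 0.5 if it
contains only hedged trigger sentences, 0.0 otherwise.

The linguistic model is deliberately simple: documents are sequences of
section-tagged paragraphs; relation-bearing sentences are drawn from three
disjoint template banks (assertive, hedged, neutral co-mention); filler
sentences are sampled from a small pseudo-vocabulary.  METHODS-like noise
paragraphs contain no entities at all, emulating experimental-protocol
text.  "Hard mode" additionally plants single-sentence co-mentions of
non-associated pairs without any trigger, so co-occurrence alone does not
separate the classes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .corpus_io import (
    Document,
    EntityClass,
    EntityMention,
    Passage,
    RelationLabel,
    SectionType,
    validate_document,
)

__all__ = ["GeneratorConfig", "make_template_bank", "generate_corpus", "inject_noise_passages"]

# Trigger templates.  {G} and {D} are the gene / disease placeholders.
# Assertive and hedged templates co-mention the pair inside one sentence;
# neutral templates mention the entities in different sentences.
_ASSERTIVE = (
    "{G} is associated with {D} .",
    "Mutations in {G} cause {D} .",
    "We found that {G} expression increases the risk of {D} .",
    "{G} is a key driver of {D} .",
    "Overexpression of {G} promotes {D} progression .",
    "Loss of {G} function leads to {D} .",
)
_HEDGED = (
    "{G} may be linked to {D} .",
    "{G} might contribute to {D} .",
    "It remains unclear whether {G} is involved in {D} .",
    "{G} could possibly play a role in {D} .",
    "A putative connection between {G} and {D} has been suggested .",
)
_NEUTRAL = (
    "{G} expression was measured in all samples . Patients with {D} were enrolled in the study .",
    "{G} was genotyped by standard assays . The cohort included {D} cases .",
    "Levels of {G} were recorded at baseline . Separately , {D} incidence was tracked .",
    "{G} transcripts were quantified . Controls without {D} were matched by age .",
)
# Hard-mode distractors: one-sentence co-mention with no trigger wording.
_DISTRACTOR = (
    "Both {G} and {D} were recorded in the registry .",
    "The dataset lists {G} measurements alongside {D} status .",
)

_FILLER_STEMS = (
    "samples were processed according to protocol",
    "statistical analysis used standard software",
    "the cohort was recruited at two centers",
    "replicates were averaged before analysis",
    "quality control removed outlier measurements",
    "reagents were obtained from commercial suppliers",
    "sequencing libraries were prepared in duplicate",
    "results were consistent across batches",
)

_GENE_STEMS = ("ZNF", "ABCX", "TPQ", "ILR", "MYCL", "KRAX", "BRCX", "EGFX")
_DISEASE_STEMS = ("carcinoma", "neuropathy", "dermatitis", "myopathy", "anemia", "fibrosis")


def make_template_bank() -> dict[str, tuple[str, ...]]:
    """Three pairwise-disjoint sentence-template banks.

    ``assertive`` and ``hedged`` templates carry both placeholders in one
    sentence (an explicit trigger phrase between them); ``neutral``
    templates split the two placeholders across at least two sentences so
    the pair co-occurs in the document but never with a trigger.
    """
    return {
        "assertive": _ASSERTIVE,
        "hedged": _HEDGED,
        "neutral": _NEUTRAL,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults emulate a small full-text article: a handful of entities, a
    title without entity mentions, abstract/intro/results/discussion
    content paragraphs, and METHODS paragraphs that are pure noise.
    """

    n_docs: int = 100
    genes_per_doc: tuple[int, int] = (1, 2)
    diseases_per_doc: tuple[int, int] = (1, 2)
    sections: tuple[tuple[SectionType, int, int], ...] = (
        (SectionType.ABSTRACT, 1, 1),
        (SectionType.INTRO, 1, 2),
        (SectionType.RESULTS, 1, 2),
        (SectionType.DISCUSS, 1, 1),
    )
    p_associated: float = 0.35
    p_ambiguous: float = 0.15
    noise_paragraph_rate: float = 0.5
    max_noise_paragraphs: int = 2
    vocabulary_size: int = 120
    hard_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_associated + self.p_ambiguous > 1.0 + 1e-12:
            raise ValueError("p_associated + p_ambiguous must be <= 1")
        if self.n_docs < 0 or self.vocabulary_size <= 0:
            raise ValueError("counts must be non-negative, vocabulary non-empty")
        for lo, hi in (self.genes_per_doc, self.diseases_per_doc):
            if lo < 1 or hi < lo:
                raise ValueError("entity count ranges must satisfy 1 <= lo <= hi")


@dataclass
class _Entity:
    concept_id: str
    surface: str
    entity_class: EntityClass


class _PassageBuilder:
    """Accumulates sentences, tracking entity spans passage-locally."""

    def __init__(self) -> None:
        self.text = ""
        self.spans: list[tuple[int, int, _Entity]] = []

    def add_sentence(self, template: str, slots: dict[str, _Entity]) -> None:
        """Render a template, recording one mention span per placeholder."""
        pos = 0
        out = self.text
        rest = template
        while rest:
            g = rest.find("{G}")
            d = rest.find("{D}")
            nxt = min(x for x in (g, d) if x >= 0) if (g >= 0 or d >= 0) else -1
            if nxt < 0:
                out += rest
                rest = ""
                break
            out += rest[:nxt]
            key = rest[nxt + 1]  # 'G' or 'D'
            ent = slots[key]
            start = len(out)
            out += ent.surface
            self.spans.append((start, len(out), ent))
            rest = rest[nxt + 3 :]
        self.text = out + " "


def _sample_vocab(rng: random.Random, size: int) -> list[str]:
    words: list[str] = []
    for stem in _FILLER_STEMS:
        words.extend(stem.split())
    i = 0
    while len(words) < size:
        words.append(f"term{i}")
        i += 1
    return words[:size]


def _filler_sentence(rng: random.Random, vocab: list[str]) -> str:
    n = rng.randint(5, 10)
    return " ".join(rng.choice(vocab) for _ in range(n)) + " ."


def _make_entities(rng: random.Random, n_genes: int, n_diseases: int, doc_seq: int) -> tuple[list[_Entity], list[_Entity]]:
    genes, diseases = [], []
    for j in range(n_genes):
        uid = doc_seq * 10 + j
        stem = rng.choice(_GENE_STEMS)
        genes.append(_Entity(f"GENE:{uid}", f"{stem}{uid}", EntityClass.GENE))
    for j in range(n_diseases):
        uid = doc_seq * 10 + j
        stem = rng.choice(_DISEASE_STEMS)
        # some multi-token surfaces to exercise span bookkeeping
        surface = f"familial {stem}{uid}" if rng.random() < 0.4 else f"{stem}{uid}"
        diseases.append(_Entity(f"MESH:D{uid}", surface, EntityClass.DISEASE))
    return genes, diseases


def generate_corpus(config: GeneratorConfig) -> tuple[list[Document], list[RelationLabel]]:
    """Generate documents plus the complete truth over all candidate pairs.

    Deterministic: identical config (including seed) yields a byte-identical
    corpus.  Associated pairs get 1-2 assertive trigger sentences, ambiguous
    pairs only hedged triggers, non-associated pairs only neutral split
    co-mentions (plus trigger-free single-sentence distractors in hard mode).
    METHODS noise paragraphs contain no entities.
    """
    rng = random.Random(config.seed)
    vocab = _sample_vocab(rng, config.vocabulary_size)
    banks = make_template_bank()
    docs: list[Document] = []
    labels: list[RelationLabel] = []

    for doc_seq in range(config.n_docs):
        doc_id = f"SYN{doc_seq:05d}"
        n_g = rng.randint(*config.genes_per_doc)
        n_d = rng.randint(*config.diseases_per_doc)
        genes, diseases = _make_entities(rng, n_g, n_d, doc_seq)

        # relation assignment per pair
        pair_rel: dict[tuple[str, str], float] = {}
        for g in genes:
            for d in diseases:
                u = rng.random()
                if u < config.p_associated:
                    rel = 1.0
                elif u < config.p_associated + config.p_ambiguous:
                    rel = 0.5
                else:
                    rel = 0.0
                pair_rel[(g.concept_id, d.concept_id)] = rel
                labels.append(
                    RelationLabel(doc_id, g.concept_id, d.concept_id, rel, "gold")
                )

        # sentence pool per pair
        pair_sentences: list[tuple[str, _Entity, _Entity]] = []
        for g in genes:
            for d in diseases:
                rel = pair_rel[(g.concept_id, d.concept_id)]
                if rel == 1.0:
                    for _ in range(rng.randint(1, 2)):
                        pair_sentences.append((rng.choice(banks["assertive"]), g, d))
                elif rel == 0.5:
                    pair_sentences.append((rng.choice(banks["hedged"]), g, d))
                else:
                    pair_sentences.append((rng.choice(banks["neutral"]), g, d))
                    if config.hard_mode and rng.random() < 0.7:
                        pair_sentences.append((rng.choice(_DISTRACTOR), g, d))
        rng.shuffle(pair_sentences)

        # content paragraphs: TITLE (entity-free) + configured sections
        content_slots: list[tuple[SectionType, int]] = []
        for sec, lo, hi in config.sections:
            for k in range(rng.randint(lo, hi)):
                content_slots.append((sec, k))
        builders = [_PassageBuilder() for _ in content_slots]
        for sent in pair_sentences:
            template, g, d = sent
            builders[rng.randrange(len(builders))].add_sentence(
                template, {"G": g, "D": d}
            )
        for b in builders:
            if rng.random() < 0.6 or not b.text:
                b.text += _filler_sentence(rng, vocab) + " "

        passages: list[Passage] = []
        mentions: list[EntityMention] = []
        offset = 0

        def push(section: SectionType, par_idx: int, builder: _PassageBuilder | None, text: str | None = None) -> None:
            nonlocal offset
            body = builder.text if builder is not None else (text or "")
            passages.append(Passage(section, par_idx, offset, body))
            if builder is not None:
                for s, e, ent in builder.spans:
                    mentions.append(
                        EntityMention(offset + s, offset + e, ent.surface,
                                      ent.entity_class, ent.concept_id)
                    )
            offset += len(body)

        push(SectionType.TITLE, 0, None, f"A study of candidate gene function in disease cohort {doc_seq} . ")
        for (sec, k), b in zip(content_slots, builders):
            push(sec, k, b)
        # METHODS noise paragraphs: entity-free by construction
        if rng.random() < config.noise_paragraph_rate:
            for k in range(rng.randint(1, max(1, config.max_noise_paragraphs))):
                noise = " ".join(_filler_sentence(rng, vocab) for _ in range(rng.randint(1, 3))) + " "
                push(SectionType.METHODS, k, None, noise)

        doc = Document(doc_id=doc_id, passages=passages, mentions=sorted(
            mentions, key=lambda m: (m.start, m.end)
        ))
        violations = validate_document(doc)
        if violations:  # pragma: no cover - generator bug guard
            raise AssertionError(f"generator produced invalid document: {violations}")
        docs.append(doc)

    return docs, labels


def inject_noise_passages(doc: Document, k: int, seed: int = 0) -> Document:
    """Insert ``k`` entity-free METHODS paragraphs at random positions.

    Passage offsets and mention spans are recomputed so the result passes
    ``validate_document``.  ``k = 0`` returns an equal document.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return Document(doc.doc_id, list(doc.passages), list(doc.mentions))
    rng = random.Random(seed)
    vocab = _sample_vocab(rng, 60)
    working = [(p, doc.mentions_in_passage(p)) for p in doc.passages]
    for i in range(k):
        text = " ".join(_filler_sentence(rng, vocab) for _ in range(rng.randint(1, 2))) + " "
        pos = rng.randint(1, len(working))  # never before the title
        noise = Passage(SectionType.METHODS, 1000 + i, 0, text)
        working.insert(pos, (noise, []))
    # rebuild with passage-local recoordination: assign provisional offsets
    passages: list[Passage] = []
    mentions: list[EntityMention] = []
    offset = 0
    for p, ms in working:
        delta = offset - p.offset
        passages.append(Passage(p.section_type, p.paragraph_index, offset, p.text))
        for m in ms:
            mentions.append(
                EntityMention(m.start + delta, m.end + delta, m.surface,
                              m.entity_class, m.concept_id)
            )
        offset += len(p.text)
    return Document(doc.doc_id, passages, sorted(mentions, key=lambda m: (m.start, m.end)))
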