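"""From validated documents to model-ready pair-conditioned instances.

Pipeline: sentence splitting and tokenization (span-safe with respect to
entity mentions), Section Filtering (SeFi: drop paragraphs without a
gene-disease pair), optional section exclusion (METHODS is excluded from
training by default), candidate-pair enumeration over concept IDs,
vocabulary construction, and encoding into fixed-width token/role grids.

The role alphabet marks each token's relation to the candidate pair:
0 none, 1 target gene, 2 target disease, 3 non-target gene, 4 non-target
disease.  Grids are capped at 1000 sentences x 54 tokens, i.e. an encoder
capacity of 54 000 tokens per document; truncation keeps the earliest
sentences and tokens, where the most informative sections (title,
abstract, introduction) live.
"""

from __future__ import annotations

import hashlib
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    Document,
    EntityClass,
    Passage,
    SectionType,
    rebuild_document,
    validate_document,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MAX_SENTENCES",
    "MAX_TOKENS_PER_SENTENCE",
    "TokenRole",
    "SentencizedDocument",
    "Vocabulary",
    "EncodedInstance",
    "split_sentences",
    "apply_section_filter",
    "drop_sections",
    "enumerate_candidate_pairs",
    "build_vocabulary",
    "encode_instance",
    "encode_document",
    "corpus_statistics",
    "round_half_up_pct",
]

MAX_SENTENCES = 1000
MAX_TOKENS_PER_SENTENCE = 54

PAD_INDEX = 0
UNK_INDEX = 1

# role-grid alphabet
ROLE_NONE = 0
ROLE_TARGET_GENE = 1
ROLE_TARGET_DISEASE = 2
ROLE_OTHER_GENE = 3
ROLE_OTHER_DISEASE = 4


class TokenRole:
    """Alias namespace for the 5-symbol role alphabet."""

    NONE = ROLE_NONE
    TARGET_GENE = ROLE_TARGET_GENE
    TARGET_DISEASE = ROLE_TARGET_DISEASE
    OTHER_GENE = ROLE_OTHER_GENE
    OTHER_DISEASE = ROLE_OTHER_DISEASE


# tokens: word characters (incl. digits) or single punctuation marks
_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
# sentence-final punctuation; split decided token-wise
_TERMINAL = {".", "!", "?"}
# abbreviation guard: a '.' directly after these tokens does not end a sentence
_ABBREV = {"al", "fig", "figs", "dr", "vs", "etc", "approx", "no", "e", "i"}


@dataclass
class SentencizedDocument:
    """Sentence/token view of a document with per-token mention links.

    ``token_roles[s][t]`` is ``None`` or ``(entity_class, concept_id)`` of
    the mention covering the token (gene wins on nested gene/disease
    conflicts, which are logged).
    """

    doc_id: str
    sentences: list[list[str]] = field(default_factory=list)
    token_roles: list[list[tuple[EntityClass, str] | None]] = field(default_factory=list)
    sentence_section: list[SectionType] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


def _tokenize_passage(
    passage: Passage, mention_bounds: list[int]
) -> list[tuple[str, int, int]]:
    """Tokens with document-global spans; boundaries forced at mention edges."""
    tokens: list[tuple[str, int, int]] = []
    base = passage.offset
    bounds = sorted(b - base for b in mention_bounds if base < b < passage.end)
    for m in _TOKEN_RE.finditer(passage.text):
        start, end = m.start(), m.end()
        cuts = [start] + [b for b in bounds if start < b < end] + [end]
        for a, b in zip(cuts, cuts[1:]):
            tokens.append((passage.text[a:b], base + a, base + b))
    return tokens


def split_sentences(doc: Document) -> SentencizedDocument:
    """Rule-based, span-safe sentence splitting and tokenization.

    Sentences end at ``. ! ?`` tokens (with an abbreviation guard) and are
    always forced closed at passage boundaries; a split never lands inside
    a mention span because token boundaries are forced at span edges and
    terminal punctuation inside a mention never terminates a sentence.
    """
    sdoc = SentencizedDocument(doc_id=doc.doc_id)
    mention_bounds = [b for m in doc.mentions for b in (m.start, m.end)]
    # interval list for role lookup; later mentions do not override genes
    sorted_mentions = sorted(doc.mentions, key=lambda m: (m.start, m.end))

    def role_of(start: int, end: int) -> tuple[EntityClass, str] | None:
        hit: tuple[EntityClass, str] | None = None
        for m in sorted_mentions:
            if m.start <= start and end <= m.end:
                cand = (m.entity_class, m.concept_id)
                if hit is None:
                    hit = cand
                elif hit[0] is not cand[0]:
                    logger.warning(
                        "doc %s: nested gene/disease mentions at [%d, %d); gene takes precedence",
                        doc.doc_id, start, end,
                    )
                    if cand[0] is EntityClass.GENE:
                        hit = cand
        return hit

    for passage in doc.passages:
        tokens = _tokenize_passage(passage, mention_bounds)
        cur_tok: list[str] = []
        cur_role: list[tuple[EntityClass, str] | None] = []
        prev_word: str | None = None

        def close() -> None:
            nonlocal cur_tok, cur_role
            if cur_tok:
                sdoc.sentences.append(cur_tok)
                sdoc.token_roles.append(cur_role)
                sdoc.sentence_section.append(passage.section_type)
            cur_tok, cur_role = [], []

        for text, start, end in tokens:
            r = role_of(start, end)
            cur_tok.append(text)
            cur_role.append(r)
            if text in _TERMINAL and r is None:
                if not (text == "." and prev_word is not None and prev_word.lower() in _ABBREV):
                    close()
            prev_word = text
        close()  # passage boundary always closes the sentence
    return sdoc


def _passage_has_pair(doc: Document, passage: Passage) -> bool:
    ms = doc.mentions_in_passage(passage)
    return any(m.entity_class is EntityClass.GENE for m in ms) and any(
        m.entity_class is EntityClass.DISEASE for m in ms
    )


def apply_section_filter(doc: Document) -> Document:
    """Section Filtering (SeFi): drop paragraphs without a gene-disease pair.

    A passage is kept iff it contains at least one gene mention and at
    least one disease mention; TITLE passages are always kept (titles are
    not paragraphs).  Offsets and spans are recomputed; the result passes
    ``validate_document``.
    """
    kept = [
        p
        for p in doc.passages
        if p.section_type is SectionType.TITLE or _passage_has_pair(doc, p)
    ]
    return rebuild_document(doc.doc_id, kept, doc.mentions)


def drop_sections(doc: Document, excluded: set[SectionType]) -> Document:
    """Remove all passages whose section type is excluded.

    The training default excludes METHODS; prediction drops nothing unless
    explicitly asked.
    """
    kept = [p for p in doc.passages if p.section_type not in excluded]
    return rebuild_document(doc.doc_id, kept, doc.mentions)


TRAINING_EXCLUDED_SECTIONS = frozenset({SectionType.METHODS})


def enumerate_candidate_pairs(doc: Document) -> list[tuple[str, str]]:
    """All unique (gene concept_id, disease concept_id) pairs in the document.

    Cartesian product over the unique concept IDs present, in lexicographic
    order (deterministic).
    """
    genes = sorted({m.concept_id for m in doc.mentions if m.entity_class is EntityClass.GENE})
    diseases = sorted({m.concept_id for m in doc.mentions if m.entity_class is EntityClass.DISEASE})
    return [(g, d) for g in genes for d in diseases]


@dataclass(frozen=True)
class Vocabulary:
    """Token-to-index map with reserved indices 0 (padding) and 1 (unknown)."""

    token_to_id: dict[str, int]

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def index(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_INDEX)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha1()
        for tok, idx in sorted(self.token_to_id.items()):
            h.update(f"{tok}\t{idx}\n".encode())
        return h.hexdigest()

    @property
    def tokens_in_index_order(self) -> list[str]:
        return [t for t, _ in sorted(self.token_to_id.items(), key=lambda kv: kv[1])]


def build_vocabulary(corpus: list[SentencizedDocument], min_count: int = 1) -> Vocabulary:
    """Frequency-thresholded vocabulary, deterministic.

    Tokens with frequency >= ``min_count`` are indexed densely from 2,
    ordered by descending frequency then lexicographically; all others map
    to the unknown index.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for sdoc in corpus:
        for sent in sdoc.sentences:
            counts.update(sent)
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count),
        key=lambda tok: (-counts[tok], tok),
    )
    return Vocabulary({tok: i + 2 for i, tok in enumerate(kept)})


@dataclass
class EncodedInstance:
    """Pair-conditioned S x T grids of token indices and role symbols."""

    doc_id: str
    pair: tuple[str, str]
    token_ids: np.ndarray  # (S, T) int32
    role_ids: np.ndarray  # (S, T) int8
    valid_lengths: np.ndarray  # (S,) int32

    @property
    def n_sentences(self) -> int:
        return self.token_ids.shape[0]


def encode_instance(
    sdoc: SentencizedDocument,
    pair: tuple[str, str],
    vocab: Vocabulary,
    max_sentences: int = MAX_SENTENCES,
    max_tokens_per_sentence: int = MAX_TOKENS_PER_SENTENCE,
) -> EncodedInstance:
    """Encode one candidate pair of a sentencized document.

    Sentences beyond ``max_sentences`` and tokens beyond
    ``max_tokens_per_sentence`` are dropped from the end.  Role symbols 1/2
    mark tokens of mentions whose concept_id equals the pair's gene/disease;
    other gene/disease mentions get 3/4.
    """
    gene_id, disease_id = pair
    present = {
        (r[0], r[1]) for roles in sdoc.token_roles for r in roles if r is not None
    }
    if (EntityClass.GENE, gene_id) not in present or (
        EntityClass.DISEASE,
        disease_id,
    ) not in present:
        raise ValueError(
            f"pair ({gene_id}, {disease_id}) is not a candidate pair of doc {sdoc.doc_id}"
        )
    sents = sdoc.sentences[:max_sentences]
    roles = sdoc.token_roles[:max_sentences]
    S, T = len(sents), max_tokens_per_sentence
    token_ids = np.zeros((S, T), dtype=np.int32)
    role_ids = np.zeros((S, T), dtype=np.int8)
    valid = np.zeros(S, dtype=np.int32)
    for s, (toks, rls) in enumerate(zip(sents, roles)):
        L = min(len(toks), T)
        valid[s] = L
        for t in range(L):
            token_ids[s, t] = vocab.index(toks[t])
            r = rls[t]
            if r is None:
                continue
            cls, cid = r
            if cls is EntityClass.GENE:
                role_ids[s, t] = ROLE_TARGET_GENE if cid == gene_id else ROLE_OTHER_GENE
            else:
                role_ids[s, t] = (
                    ROLE_TARGET_DISEASE if cid == disease_id else ROLE_OTHER_DISEASE
                )
    return EncodedInstance(sdoc.doc_id, pair, token_ids, role_ids, valid)


def encode_document(
    sdoc: SentencizedDocument,
    pairs: list[tuple[str, str]],
    vocab: Vocabulary,
    **limits: int,
) -> list[EncodedInstance]:
    return [encode_instance(sdoc, pair, vocab, **limits) for pair in pairs]


def round_half_up_pct(numerator: int, denominator: int) -> float | None:
    """Percentage with one decimal, round-half-up; None when undefined."""
    if denominator == 0:
        return None
    from decimal import ROUND_HALF_UP, Decimal

    pct = Decimal(numerator) / Decimal(denominator) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def corpus_statistics(corpus: list[Document], labels=None, top_k: int = 3) -> dict:
    """Descriptive statistics in the style of a corpus table.

    Totals count per-document unique concept IDs / ID pairs summed over
    documents; "unique" counts the corpus-wide union.  The unique-to-total
    pair percentage is reported with one decimal (round half up), or None
    for an empty corpus.  Mention-pair totals (gene mentions x disease
    mentions per document) are also reported.
    """
    gene_mentions = disease_mentions = 0
    total_genes = total_diseases = total_pairs = 0
    mention_pair_total = 0
    uniq_genes: set[str] = set()
    uniq_diseases: set[str] = set()
    uniq_pairs: set[tuple[str, str]] = set()
    gene_docs: Counter[str] = Counter()
    disease_docs: Counter[str] = Counter()
    pair_docs: Counter[tuple[str, str]] = Counter()
    for doc in corpus:
        g_ids = {m.concept_id for m in doc.mentions if m.entity_class is EntityClass.GENE}
        d_ids = {m.concept_id for m in doc.mentions if m.entity_class is EntityClass.DISEASE}
        n_gm = sum(1 for m in doc.mentions if m.entity_class is EntityClass.GENE)
        n_dm = sum(1 for m in doc.mentions if m.entity_class is EntityClass.DISEASE)
        gene_mentions += n_gm
        disease_mentions += n_dm
        mention_pair_total += n_gm * n_dm
        total_genes += len(g_ids)
        total_diseases += len(d_ids)
        total_pairs += len(g_ids) * len(d_ids)
        uniq_genes |= g_ids
        uniq_diseases |= d_ids
        uniq_pairs |= {(g, d) for g in g_ids for d in d_ids}
        gene_docs.update(g_ids)
        disease_docs.update(d_ids)
        pair_docs.update((g, d) for g in g_ids for d in d_ids)
    stats = {
        "n_docs": len(corpus),
        "gene_mentions": gene_mentions,
        "disease_mentions": disease_mentions,
        "total_genes": total_genes,
        "total_diseases": total_diseases,
        "unique_genes": len(uniq_genes),
        "unique_diseases": len(uniq_diseases),
        "total_pairs": total_pairs,
        "unique_pairs": len(uniq_pairs),
        "mention_pair_total": mention_pair_total,
        "unique_to_total_pct": round_half_up_pct(len(uniq_pairs), total_pairs),
        "unique_to_mention_pair_pct": round_half_up_pct(len(uniq_pairs), mention_pair_total),
        "top_genes": gene_docs.most_common(top_k),
        "top_diseases": disease_docs.most_common(top_k),
        "top_pairs": pair_docs.most_common(top_k),
    }
    if labels is not None:
        by_target = Counter(l.gdp_target for l in labels)
        stats["labels"] = {
            "associated": by_target.get(1.0, 0),
            "ambiguous": by_target.get(0.5, 0),
            "non_associated": by_target.get(0.0, 0),
        }
    return stats
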