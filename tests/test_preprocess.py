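import re

import numpy as np
import pytest

from renet_ft.corpus_io import EntityClass, SectionType
from renet_ft.preprocess import (
    MAX_SENTENCES,
    MAX_TOKENS_PER_SENTENCE,
    SentencizedDocument,
    TokenRole,
    apply_section_filter,
    build_vocabulary,
    corpus_statistics,
    drop_sections,
    encode_instance,
    enumerate_candidate_pairs,
    round_half_up_pct,
    split_sentences,
)

from conftest import build_doc


class TestSplitSentences:
    def test_single_sentence_with_roles(self, simple_doc):
        sdoc = split_sentences(simple_doc)
        assert sdoc.sentences == [["BRCA1", "causes", "cancer", "."]]
        roles = sdoc.token_roles[0]
        assert roles[0] == (EntityClass.GENE, "GENE:1")
        assert roles[2] == (EntityClass.DISEASE, "MESH:D1")
        assert roles[1] is None and roles[3] is None
        assert sdoc.sentence_section == [SectionType.TITLE]

    def test_empty_passage_contributes_no_sentences(self):
        doc = build_doc("D1", [(SectionType.TITLE, "One sentence . "), (SectionType.INTRO, "")])
        assert len(split_sentences(doc).sentences) == 1

    def test_passage_boundary_forces_sentence_break(self):
        doc = build_doc(
            "D1",
            [(SectionType.TITLE, "no terminal punctuation here "),
             (SectionType.INTRO, "second passage text . ")],
        )
        sdoc = split_sentences(doc)
        assert len(sdoc.sentences) == 2
        assert sdoc.sentence_section == [SectionType.TITLE, SectionType.INTRO]

    def test_abbreviation_guard(self):
        doc = build_doc("D1", [(SectionType.INTRO, "As shown by Smith et al . the effect is large . ")])
        assert len(split_sentences(doc).sentences) == 1

    def test_mention_boundary_forces_token_split(self):
        # mention covers only part of what the tokenizer would call a token
        doc = build_doc(
            "D1",
            [(SectionType.INTRO, "the TP53mut allele in tumors . ")],
            [(4, 8, "Gene", "GENE:2")],
        )
        sdoc = split_sentences(doc)
        assert "TP53" in sdoc.sentences[0]
        idx = sdoc.sentences[0].index("TP53")
        assert sdoc.token_roles[0][idx] == (EntityClass.GENE, "GENE:2")
        assert sdoc.sentences[0][idx + 1] == "mut"

    def test_token_count_conserved_against_independent_recount(self, small_corpus):
        token_re = re.compile(r"\w+|[^\w\s]")
        docs, _ = small_corpus
        for doc in docs:
            sdoc = split_sentences(doc)
            # oracle: regex tokens over the full text, plus one extra token per
            # mention boundary strictly inside a regex token
            text = doc.text
            spans = [(m.start(), m.end()) for m in token_re.finditer(text)]
            bounds = {b for m in doc.mentions for b in (m.start, m.end)}
            extra = sum(1 for (a, b) in spans for cut in bounds if a < cut < b)
            assert sdoc.n_tokens == len(spans) + extra


class TestSectionFilter:
    def _brute_force(self, doc):
        """Independent per-paragraph mention-class scan."""
        kept = []
        for p in doc.passages:
            classes = {
                m.entity_class
                for m in doc.mentions
                if p.offset <= m.start and m.end <= p.end
            }
            if p.section_type is SectionType.TITLE or classes == {
                EntityClass.GENE,
                EntityClass.DISEASE,
            }:
                kept.append(p.text)
        return kept

    def test_paragraph_with_genes_only_removed(self):
        doc = build_doc(
            "D1",
            [(SectionType.TITLE, "title . "),
             (SectionType.INTRO, "TP53 and EGFR were studied . ")],
            [(8, 12, "Gene", "GENE:1"), (17, 21, "Gene", "GENE:2")],
        )
        out = apply_section_filter(doc)
        assert [p.section_type for p in out.passages] == [SectionType.TITLE]

    def test_paragraph_with_pair_kept(self, simple_doc):
        doc = build_doc(
            "D1",
            [(SectionType.INTRO, "BRCA1 causes cancer . ")],
            [(0, 5, "Gene", "GENE:1"), (13, 19, "Disease", "MESH:D1")],
        )
        out = apply_section_filter(doc)
        assert len(out.passages) == 1

    def test_matches_brute_force_oracle_on_synthetic_corpus(self, midsize_corpus):
        docs, _ = midsize_corpus
        for doc in docs:
            filtered = apply_section_filter(doc)
            assert [p.text for p in filtered.passages] == self._brute_force(doc)
            assert filtered.doc_id == doc.doc_id

    def test_idempotent(self, midsize_corpus):
        docs, _ = midsize_corpus
        for doc in docs[:10]:
            once = apply_section_filter(doc)
            twice = apply_section_filter(once)
            assert once.passages == twice.passages
            assert once.mentions == twice.mentions

    def test_filtered_documents_validate_and_conserve_mentions(self, midsize_corpus):
        from renet_ft.corpus_io import validate_document

        docs, _ = midsize_corpus
        for doc in docs:
            out = apply_section_filter(doc)
            assert validate_document(out) == []
            removed_spans = [
                (p.offset, p.end) for p in doc.passages
                if p.text not in {q.text for q in out.passages}
            ]
            lost = len(doc.mentions) - len(out.mentions)
            in_removed = sum(
                1 for m in doc.mentions
                if any(a <= m.start and m.end <= b for a, b in removed_spans)
            )
            assert lost == in_removed


class TestDropSections:
    def test_empty_exclusion_is_identity(self, simple_doc):
        out = drop_sections(simple_doc, set())
        assert out.passages == simple_doc.passages
        assert out.mentions == simple_doc.mentions

    def test_methods_passages_removed(self, midsize_corpus):
        docs, _ = midsize_corpus
        doc = next(
            d for d in docs
            if any(p.section_type is SectionType.METHODS for p in d.passages)
        )
        n_methods = sum(1 for p in doc.passages if p.section_type is SectionType.METHODS)
        out = drop_sections(doc, {SectionType.METHODS})
        assert len(out.passages) == len(doc.passages) - n_methods
        assert not any(p.section_type is SectionType.METHODS for p in out.passages)


class TestCandidatePairs:
    def test_cartesian_product_in_lexicographic_order(self):
        doc = build_doc(
            "D1",
            [(SectionType.INTRO, "aa bb cc dd ee . ")],
            [(0, 2, "Gene", "G2"), (3, 5, "Gene", "G1"),
             (6, 8, "Disease", "M1"), (9, 11, "Disease", "M3"), (12, 14, "Disease", "M2")],
        )
        pairs = enumerate_candidate_pairs(doc)
        assert pairs == [("G1", "M1"), ("G1", "M2"), ("G1", "M3"),
                         ("G2", "M1"), ("G2", "M2"), ("G2", "M3")]

    def test_no_genes_gives_empty(self):
        doc = build_doc("D1", [(SectionType.INTRO, "dd . ")], [(0, 2, "Disease", "M1")])
        assert enumerate_candidate_pairs(doc) == []

    def test_duplicate_mentions_counted_once(self):
        doc = build_doc(
            "D1",
            [(SectionType.INTRO, "aa aa dd . ")],
            [(0, 2, "Gene", "G1"), (3, 5, "Gene", "G1"), (6, 8, "Disease", "M1")],
        )
        assert enumerate_candidate_pairs(doc) == [("G1", "M1")]


class TestVocabulary:
    def _sdoc(self, *sentences):
        return SentencizedDocument(
            doc_id="D1",
            sentences=[list(s) for s in sentences],
            token_roles=[[None] * len(s) for s in sentences],
            sentence_section=[SectionType.INTRO] * len(sentences),
        )

    def test_min_count_threshold(self):
        vocab = build_vocabulary([self._sdoc(["a", "a", "b"])], min_count=2)
        assert vocab.index("a") >= 2
        assert vocab.index("b") == 1  # unknown

    def test_all_unique_tokens_below_threshold(self):
        vocab = build_vocabulary([self._sdoc(["a", "b", "c"])], min_count=2)
        assert len(vocab) == 2  # only reserved indices

    def test_deterministic_assignment(self, small_corpus):
        docs, _ = small_corpus
        sdocs = [split_sentences(d) for d in docs]
        assert build_vocabulary(sdocs).token_to_id == build_vocabulary(sdocs).token_to_id

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


class TestEncodeInstance:
    def _setup(self, text, mentions):
        doc = build_doc("D1", [(SectionType.INTRO, text)], mentions)
        sdoc = split_sentences(doc)
        vocab = build_vocabulary([sdoc])
        return doc, sdoc, vocab

    def test_role_grid_marks_target_runs(self):
        _, sdoc, vocab = self._setup(
            "BRCA1 causes cancer . ",
            [(0, 5, "Gene", "GENE:1"), (13, 19, "Disease", "MESH:D1")],
        )
        inst = encode_instance(sdoc, ("GENE:1", "MESH:D1"), vocab)
        row = inst.role_ids[0, :4].tolist()
        assert row == [TokenRole.TARGET_GENE, 0, TokenRole.TARGET_DISEASE, 0]

    def test_nontarget_gene_marked(self):
        _, sdoc, vocab = self._setup(
            "BRCA1 and TP53 cause cancer . ",
            [(0, 5, "Gene", "GENE:1"), (10, 14, "Gene", "GENE:2"),
             (21, 27, "Disease", "MESH:D1")],
        )
        inst = encode_instance(sdoc, ("GENE:1", "MESH:D1"), vocab)
        assert inst.role_ids[0, 2] == TokenRole.OTHER_GENE

    def test_long_sentence_truncated_to_limit(self):
        words = " ".join(f"w{i}" for i in range(60))
        _, sdoc, vocab = self._setup(
            "BRCA1 causes cancer . " + words + " ",
            [(0, 5, "Gene", "GENE:1"), (13, 19, "Disease", "MESH:D1")],
        )
        inst = encode_instance(sdoc, ("GENE:1", "MESH:D1"), vocab)
        assert inst.valid_lengths[1] == MAX_TOKENS_PER_SENTENCE

    def test_absent_pair_rejected(self):
        _, sdoc, vocab = self._setup(
            "BRCA1 causes cancer . ",
            [(0, 5, "Gene", "GENE:1"), (13, 19, "Disease", "MESH:D1")],
        )
        with pytest.raises(ValueError, match="not a candidate pair"):
            encode_instance(sdoc, ("GENE:9", "MESH:D1"), vocab)

    def test_capacity_is_54000_tokens(self):
        n_sent, n_tok = MAX_SENTENCES + 1, MAX_TOKENS_PER_SENTENCE + 6
        sentences = [[f"t{i}" for i in range(n_tok)] for _ in range(n_sent)]
        roles = [[None] * n_tok for _ in range(n_sent)]
        roles[0][0] = (EntityClass.GENE, "G1")
        roles[0][1] = (EntityClass.DISEASE, "M1")
        sdoc = SentencizedDocument(
            "D1", sentences, roles, [SectionType.INTRO] * n_sent
        )
        vocab = build_vocabulary([sdoc])
        inst = encode_instance(sdoc, ("G1", "M1"), vocab)
        assert inst.token_ids.shape == (MAX_SENTENCES, MAX_TOKENS_PER_SENTENCE)
        assert inst.token_ids.size == 54_000


class TestCorpusStatistics:
    def test_unique_to_total_percentage_round_half_up(self):
        assert round_half_up_pct(46_379, 51_642) == 89.8
        assert round_half_up_pct(2_568, 2_813) == 91.3
        assert round_half_up_pct(1, 3) == 33.3
        assert round_half_up_pct(1, 0) is None

    def test_duplicated_mention_pair(self):
        doc = build_doc(
            "D1",
            [(SectionType.INTRO, "aa aa dd . ")],
            [(0, 2, "Gene", "G1"), (3, 5, "Gene", "G1"), (6, 8, "Disease", "M1")],
        )
        stats = corpus_statistics([doc])
        assert stats["mention_pair_total"] == 2
        assert stats["unique_pairs"] == 1
        assert stats["unique_to_mention_pair_pct"] == 50.0

    def test_empty_corpus_reports_na(self):
        stats = corpus_statistics([])
        assert stats["n_docs"] == 0
        assert stats["unique_to_total_pct"] is None

    def test_totals_on_synthetic_corpus(self, small_corpus):
        docs, labels = small_corpus
        stats = corpus_statistics(docs, labels)
        per_doc = sum(
            len({m.concept_id for m in d.mentions if m.entity_class is EntityClass.GENE})
            * len({m.concept_id for m in d.mentions if m.entity_class is EntityClass.DISEASE})
            for d in docs
        )
        assert stats["total_pairs"] == per_doc == len(labels)
        assert stats["unique_pairs"] <= stats["total_pairs"]
        assert len(stats["top_genes"]) <= 3
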