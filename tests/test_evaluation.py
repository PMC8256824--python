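import itertools

import pytest

from renet_ft.corpus_io import PredictionRecord, RelationLabel, SectionType
from renet_ft.evaluation import (
    classify_tp_fp,
    evaluate_predictions,
    f1_score,
    make_splits,
    precision_recall_f1,
    recall_against_annotations,
    section_association_counts,
    section_overlap_rate,
    section_recall_breakdown,
)

from conftest import build_doc


def pos(doc, gene, dis, method="renet-ft"):
    return PredictionRecord(doc, gene, dis, 0.9, 1, method)


class TestSplits:
    def test_partition_folds_cover_documents_disjointly(self):
        ids = [f"d{i}" for i in range(100)]
        plan = make_splits(ids, k=5, seed=3)
        val_union = set()
        for train, val in plan.folds:
            assert len(val) == 20
            assert set(train) & set(val) == set()
            assert set(train) | set(val) == set(ids)
            val_union |= set(val)
        assert val_union == set(ids)

    def test_same_seed_reproduces_plan(self):
        ids = [f"d{i}" for i in range(40)]
        assert make_splits(ids, seed=9) == make_splits(ids, seed=9)

    def test_unbalanced_partition_sizes_differ_by_at_most_one(self):
        plan = make_splits([f"d{i}" for i in range(101)], k=5, seed=0)
        sizes = [len(val) for _, val in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 101

    def test_resample_scheme_draws_twenty_percent(self):
        plan = make_splits([f"d{i}" for i in range(50)], k=5, seed=0, scheme="resample")
        assert all(len(val) == 10 for _, val in plan.folds)

    def test_too_few_documents_rejected(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b"], k=5)


class TestCompositeTPRule:
    def test_validation_match_is_tp(self):
        tp, fp, audit = classify_tp_fp(
            [pos("d1", "g1", "m1")], [RelationLabel("d1", "g1", "m1", 1.0)], []
        )
        assert (tp, fp) == (1, 0)
        assert audit[0]["clause"] == "validation_match"

    def test_unlabeled_unanimous_is_tp(self):
        ext = [pos("d1", "g1", "m1", m) for m in ("a", "b", "c")]
        tp, fp, audit = classify_tp_fp([pos("d1", "g1", "m1")], [], ext)
        assert (tp, fp) == (1, 0)
        assert audit[0]["clause"] == "unanimous_methods"

    def test_negative_label_without_unanimity_is_fp(self):
        ext = [pos("d1", "g1", "m1", "a"), PredictionRecord("d1", "g1", "m1", 0.1, 0, "b")]
        tp, fp, _ = classify_tp_fp(
            [pos("d1", "g1", "m1")], [RelationLabel("d1", "g1", "m1", 0.0)], ext
        )
        assert (tp, fp) == (0, 1)

    def test_ambiguous_label_excluded_from_both_counts(self):
        tp, fp, audit = classify_tp_fp(
            [pos("d1", "g1", "m1")], [RelationLabel("d1", "g1", "m1", 0.5)], []
        )
        assert (tp, fp) == (0, 0)
        assert audit[0]["outcome"] == "excluded"

    def test_matches_truth_table_oracle(self):
        """Exhaustive label x external-vote combinations for 3 methods."""
        triple = ("d1", "g1", "m1")
        for target, votes in itertools.product(
            (None, 0.0, 0.5, 1.0), itertools.product((0, 1), repeat=3)
        ):
            labels = [] if target is None else [RelationLabel(*triple, target)]
            ext = [
                PredictionRecord(*triple, float(v), v, f"m{i}")
                for i, v in enumerate(votes)
            ]
            tp, fp, _ = classify_tp_fp([pos(*triple)], labels, ext)
            # independent statement of the rule
            if target == 1.0:
                expect = (1, 0)
            elif target == 0.5:
                expect = (0, 0)
            elif all(v == 1 for v in votes):
                expect = (1, 0)
            else:
                expect = (0, 1)
            assert (tp, fp) == expect, (target, votes)


class TestRecall:
    LABELS = [RelationLabel("d1", f"g{i}", "m1", 1.0) for i in range(4)] + [
        RelationLabel("d1", "g9", "m1", 0.5)
    ]

    def test_all_predicted(self):
        preds = [pos("d1", f"g{i}", "m1") for i in range(4)]
        assert recall_against_annotations(preds, self.LABELS) == (4, 0)

    def test_none_predicted(self):
        assert recall_against_annotations([], self.LABELS) == (0, 4)

    def test_three_of_four(self):
        preds = [pos("d1", f"g{i}", "m1") for i in range(3)]
        tp, fn = recall_against_annotations(preds, self.LABELS)
        assert (tp, fn) == (3, 1)
        assert tp / (tp + fn) == 0.75

    def test_ambiguous_label_not_in_denominator(self):
        preds = [pos("d1", "g9", "m1")]
        assert recall_against_annotations(preds, self.LABELS) == (0, 4)


class TestPrecisionRecallF1:
    def test_f1_from_full_text_benchmark_precision_recall(self):
        assert f1_score(0.7062, 0.7371) == pytest.approx(0.7213, abs=5e-5)

    def test_f1_high_sensitivity_row(self):
        assert f1_score(0.5518, 0.9217) == pytest.approx(0.6903, abs=5e-5)

    def test_all_zero_counts_reported_as_na(self):
        report = precision_recall_f1(0, 0, 0)
        assert report.precision is None and report.recall is None and report.f1 is None

    @pytest.mark.parametrize("tp,fp,fn", [(5, 3, 2), (1, 0, 0), (10, 10, 10), (0, 4, 7)])
    def test_f1_is_harmonic_mean(self, tp, fp, fn):
        r = precision_recall_f1(tp, fp, fn)
        if r.precision and r.recall:
            assert abs(r.f1 - 2 * r.precision * r.recall / (r.precision + r.recall)) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)

    def test_evaluate_predictions_end_to_end(self):
        labels = [
            RelationLabel("d1", "g1", "m1", 1.0),
            RelationLabel("d1", "g2", "m1", 1.0),
            RelationLabel("d1", "g3", "m1", 0.0),
        ]
        preds = [pos("d1", "g1", "m1"), pos("d1", "g3", "m1")]
        report = evaluate_predictions(preds, labels)
        assert report.tp == 1 and report.fp == 1
        assert report.recall == 0.5


SECTION_DOC = build_doc(
    "D1",
    [
        (SectionType.ABSTRACT, "BRCA1 causes cancer . "),
        (SectionType.INTRO, "TP53 links anemia . "),
        (SectionType.DISCUSS, "TP53 links anemia . "),
    ],
    [
        (0, 5, "Gene", "G1"), (13, 19, "Disease", "M1"),
        (22, 26, "Gene", "G2"), (33, 39, "Disease", "M2"),
        (42, 46, "Gene", "G2"), (53, 59, "Disease", "M2"),
    ],
)


class TestSectionAnalyses:
    def test_single_section_comention(self):
        counts = section_association_counts([pos("D1", "G1", "M1")], [SECTION_DOC])
        assert counts[SectionType.ABSTRACT] == 1
        assert sum(counts.values()) == 1

    def test_multi_section_attribution(self):
        counts = section_association_counts([pos("D1", "G2", "M2")], [SECTION_DOC])
        assert counts[SectionType.INTRO] == 1
        assert counts[SectionType.DISCUSS] == 1

    def test_empty_predictions_all_zero(self):
        counts = section_association_counts([], [SECTION_DOC])
        assert all(v == 0 for v in counts.values())

    def test_overlap_rate(self):
        assert section_overlap_rate({"a"}, {"a"}) == 1.0
        assert section_overlap_rate({"a"}, {"b"}) == 0.0
        assert section_overlap_rate({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(2 / 3)
        assert section_overlap_rate(set(), {"a"}) is None

    def test_recall_breakdown(self):
        labels = [
            RelationLabel("D1", "G1", "M1", 1.0),
            RelationLabel("D1", "G2", "M2", 1.0),
        ]
        preds = {"model": [pos("D1", "G1", "M1")]}
        out = section_recall_breakdown(preds, [SECTION_DOC], labels)["model"]
        assert out[SectionType.ABSTRACT] == 1.0
        assert out[SectionType.INTRO] == 0.0
        assert out[SectionType.METHODS] is None

    def test_per_section_tp_at_least_overall(self):
        labels = [RelationLabel("D1", "G2", "M2", 1.0)]
        preds = {"m": [pos("D1", "G2", "M2")]}
        out = section_recall_breakdown(preds, [SECTION_DOC], labels)["m"]
        per_section_tp = sum(1 for v in out.values() if v == 1.0)
        assert per_section_tp >= 1  # multi-attribution counts the pair twice
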