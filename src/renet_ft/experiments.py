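"""Reproducible synthetic benchmarks used by the test suite and scripts.

The label-recovery experiment is the package's end-to-end check: generate
a separable synthetic corpus (assertive triggers only, no ambiguous
pairs), train a seeded ensemble at reduced model size, and measure
precision/recall/F1 of single members, the majority-vote ensemble, and
the any-positive high-sensitivity vote against the complete held-out
truth.  Problem sizes (300 training / 100 test documents, ensemble of 10)
are the package's standard configuration for this benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import Document, RelationLabel
from .ensemble import (
    DEFAULT_MODE,
    HIGH_SENSITIVITY_MODE,
    EnsembleConfig,
    ensemble_predict,
    train_ensemble,
)
from .evaluation import MetricsReport, precision_recall_f1
from .model import ModelConfig, score_instances
from .preprocess import (
    TRAINING_EXCLUDED_SECTIONS,
    EncodedInstance,
    Vocabulary,
    apply_section_filter,
    build_vocabulary,
    drop_sections,
    encode_document,
    enumerate_candidate_pairs,
    split_sentences,
)
from .synthetic_corpus import GeneratorConfig, generate_corpus

__all__ = ["LabelRecoveryResult", "prepare_instances", "run_label_recovery"]


def prepare_instances(
    docs: list[Document],
    vocab: Vocabulary | None = None,
    training: bool = False,
    sefi: bool = True,
) -> tuple[list[EncodedInstance], Vocabulary]:
    """Default preprocessing: METHODS dropped for training only, then SeFi."""
    processed = []
    for d in docs:
        if training:
            d = drop_sections(d, set(TRAINING_EXCLUDED_SECTIONS))
        if sefi:
            d = apply_section_filter(d)
        processed.append(d)
    sdocs = [split_sentences(d) for d in processed]
    if vocab is None:
        vocab = build_vocabulary(sdocs)
    instances = [
        inst
        for sdoc, d in zip(sdocs, processed)
        for inst in encode_document(sdoc, enumerate_candidate_pairs(d), vocab)
    ]
    return instances, vocab


def _score_against_truth(
    called_positive: set[tuple[str, str, str]],
    truth: dict[tuple[str, str, str], float],
    universe: list[tuple[str, str, str]],
) -> MetricsReport:
    tp = sum(1 for t in universe if t in called_positive and truth[t] == 1.0)
    fp = sum(1 for t in universe if t in called_positive and truth[t] != 1.0)
    fn = sum(1 for t in universe if t not in called_positive and truth[t] == 1.0)
    return precision_recall_f1(tp, fp, fn)


@dataclass
class LabelRecoveryResult:
    member_reports: list[MetricsReport]
    ensemble_report: MetricsReport
    high_sensitivity_report: MetricsReport
    hs_calls_superset_of_default: bool
    n_train_instances: int
    n_test_instances: int

    @property
    def mean_member_f1(self) -> float:
        vals = [r.f1 for r in self.member_reports if r.f1 is not None]
        return sum(vals) / len(vals)


def run_label_recovery(
    seed: int,
    n_train: int = 300,
    n_test: int = 100,
    theta: int = 10,
    model_config: ModelConfig | None = None,
) -> LabelRecoveryResult:
    """Train a theta-member ensemble on separable synthetic data and score it."""
    gen = GeneratorConfig(
        n_docs=n_train + n_test, p_ambiguous=0.0, hard_mode=True, seed=seed
    )
    docs, labels = generate_corpus(gen)
    truth = {l.triple: l.gdp_target for l in labels}
    train_docs, test_docs = docs[:n_train], docs[n_train:]

    train_instances, vocab = prepare_instances(train_docs, training=True)
    test_instances, _ = prepare_instances(test_docs, vocab=vocab, training=False)

    mc = model_config or ModelConfig.small()
    ens = EnsembleConfig(theta=theta, seeds=tuple(seed + i for i in range(theta)))
    models = train_ensemble(train_instances, labels, mc, ens, len(vocab))

    per_model = [score_instances(m, test_instances) for m in models]
    universe = [(i.doc_id, *i.pair) for i in test_instances]
    member_reports = [
        _score_against_truth({r.triple for r in recs if r.call == 1}, truth, universe)
        for recs in per_model
    ]
    default_preds = ensemble_predict(per_model, mode=DEFAULT_MODE)
    hs_preds = ensemble_predict(per_model, mode=HIGH_SENSITIVITY_MODE)
    default_pos = {r.triple for r in default_preds if r.call == 1}
    hs_pos = {r.triple for r in hs_preds if r.call == 1}
    return LabelRecoveryResult(
        member_reports=member_reports,
        ensemble_report=_score_against_truth(default_pos, truth, universe),
        high_sensitivity_report=_score_against_truth(hs_pos, truth, universe),
        hs_calls_superset_of_default=default_pos <= hs_pos,
        n_train_instances=len(train_instances),
        n_test_instances=len(test_instances),
    )
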