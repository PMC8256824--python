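"""Evaluation statistics for document-level gene-disease extraction.

Precision uses a composite true-positive rule that tolerates incomplete
annotation of full-text corpora: a positive prediction is a true positive
if (i) the pair carries an associated (1.0) validation label, or (ii)
every supplied method — this tool plus the external baselines — calls it
associated.  Recall is counted against the annotated associations only.
Ambiguous (0.5) labels are introduced for training; evaluation excludes
them from both the recall denominator and the precision numerator (a
positive prediction on an ambiguous pair is neither TP nor FP, logged).

Also here: seeded document-level cross-validation splits and the
section-level analyses (association counts per section, the overlap rate
|A∩B| / min(|A|, |B|) between the association sets of two sections, and
per-section recall breakdowns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, PredictionRecord, RelationLabel, SectionType
from .preprocess import EntityClass, split_sentences

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "make_splits",
    "classify_tp_fp",
    "recall_against_annotations",
    "precision_recall_f1",
    "evaluate_predictions",
    "section_association_counts",
    "section_overlap_rate",
    "section_recall_breakdown",
    "f1_score",
]

Triple = tuple[str, str, str]


@dataclass(frozen=True)
class SplitPlan:
    """k document-level (train, validation) partitions."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int
    scheme: str

    @property
    def k(self) -> int:
        return len(self.folds)


def make_splits(
    doc_ids: list[str],
    k: int = 5,
    train_frac: float = 0.8,
    seed: int = 0,
    scheme: str = "partition",
) -> SplitPlan:
    """Seeded 80/20 document-level splits.

    ``scheme="partition"`` (default): one shuffle, k disjoint validation
    folds whose sizes differ by at most one — the usual reading of k-fold
    cross-validation.  ``scheme="resample"``: k independent random
    ``1 - train_frac`` validation draws, for fidelity to "randomly picked
    80% training and 20% validation" taken literally.
    """
    ids = sorted(set(doc_ids))
    if len(ids) < k:
        raise ValueError(f"need at least {k} documents, got {len(ids)}")
    rng = np.random.default_rng(seed)
    folds = []
    if scheme == "partition":
        order = [ids[i] for i in rng.permutation(len(ids))]
        parts = [list(p) for p in np.array_split(order, k)]
        for i in range(k):
            val = tuple(sorted(parts[i]))
            train = tuple(sorted(x for j, p in enumerate(parts) if j != i for x in p))
            folds.append((train, val))
    elif scheme == "resample":
        n_val = max(1, round(len(ids) * (1 - train_frac)))
        for _ in range(k):
            order = [ids[i] for i in rng.permutation(len(ids))]
            val = tuple(sorted(order[:n_val]))
            train = tuple(sorted(order[n_val:]))
            folds.append((train, val))
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    return SplitPlan(folds=tuple(folds), seed=seed, scheme=scheme)


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    per_repeat: list["MetricsReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def f1_score(precision: float, recall: float) -> float | None:
    """Harmonic mean of precision and recall; None when undefined."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def precision_recall_f1(tp: int, fp: int, fn: int) -> MetricsReport:
    """Precision, recall and F1 from counts; undefined ratios become None."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f1 = (
        f1_score(precision, recall)
        if precision is not None and recall is not None
        else None
    )
    return MetricsReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


def classify_tp_fp(
    positive_preds: list[PredictionRecord] | list[Triple],
    validation_labels: list[RelationLabel] | dict[Triple, float],
    external_preds: list[PredictionRecord] | None = None,
) -> tuple[int, int, list[dict]]:
    """Composite true-positive rule with a per-pair audit trail.

    A positive prediction is TP iff (i) the pair carries an associated
    (1.0) validation label, or (ii) every supplied external method also
    calls it associated (the predicting tool itself is positive by
    construction).  Ambiguous (0.5) labels exclude the pair from both
    counts.  Everything else is FP.  The audit trail records which clause
    fired for each pair.
    """
    triples = [p.triple if isinstance(p, PredictionRecord) else tuple(p) for p in positive_preds]
    labels = (
        validation_labels
        if isinstance(validation_labels, dict)
        else {l.triple: l.gdp_target for l in validation_labels}
    )
    by_method: dict[str, dict[Triple, int]] = {}
    for r in external_preds or []:
        by_method.setdefault(r.method, {})[r.triple] = r.call
    tp = fp = 0
    audit: list[dict] = []
    for t in triples:
        target = labels.get(t)
        if target == 1.0:
            tp += 1
            audit.append({"triple": t, "outcome": "TP", "clause": "validation_match"})
            continue
        if target == 0.5:
            logger.info("positive prediction on ambiguous-labeled pair %s excluded", t)
            audit.append({"triple": t, "outcome": "excluded", "clause": "ambiguous_label"})
            continue
        if by_method and all(calls.get(t, 0) == 1 for calls in by_method.values()):
            tp += 1
            audit.append({"triple": t, "outcome": "TP", "clause": "unanimous_methods"})
            continue
        fp += 1
        audit.append({"triple": t, "outcome": "FP", "clause": "none"})
    return tp, fp, audit


def recall_against_annotations(
    positive_preds: list[PredictionRecord] | list[Triple],
    validation_labels: list[RelationLabel] | dict[Triple, float],
) -> tuple[int, int]:
    """(correctly predicted annotated associations, missed ones).

    The denominator is the associated (1.0) validation labels; ambiguous
    labels count on neither side.
    """
    pred_triples = {
        p.triple if isinstance(p, PredictionRecord) else tuple(p) for p in positive_preds
    }
    labels = (
        validation_labels
        if isinstance(validation_labels, dict)
        else {l.triple: l.gdp_target for l in validation_labels}
    )
    annotated = {t for t, target in labels.items() if target == 1.0}
    tp_recall = len(annotated & pred_triples)
    return tp_recall, len(annotated) - tp_recall


def evaluate_predictions(
    preds: list[PredictionRecord],
    validation_labels: list[RelationLabel],
    external_preds: list[PredictionRecord] | None = None,
) -> MetricsReport:
    """End-to-end report: composite precision, annotation recall, F1."""
    positives = [p for p in preds if p.call == 1]
    tp, fp, _ = classify_tp_fp(positives, validation_labels, external_preds)
    tp_recall, fn = recall_against_annotations(positives, validation_labels)
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp_recall / (tp_recall + fn) if tp_recall + fn > 0 else None
    f1 = (
        f1_score(precision, recall)
        if precision is not None and recall is not None
        else None
    )
    return MetricsReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1)


# ---------------------------------------------------------------------------
# Section-level analyses
# ---------------------------------------------------------------------------


def _co_mention_sections(
    doc: Document, gene_id: str, disease_id: str
) -> set[SectionType]:
    """Sections with >= 1 sentence containing both target entities."""
    sdoc = split_sentences(doc)
    out: set[SectionType] = set()
    for roles, section in zip(sdoc.token_roles, sdoc.sentence_section):
        ents = {r for r in roles if r is not None}
        if (EntityClass.GENE, gene_id) in ents and (EntityClass.DISEASE, disease_id) in ents:
            out.add(section)
    return out


def section_association_counts(
    positive_preds: list[PredictionRecord], corpus: list[Document]
) -> dict[SectionType, int]:
    """Count positive predictions per section via sentence co-mention.

    A predicted association is attributed to every section that has at
    least one sentence co-mentioning the pair, so one prediction may
    increment several sections.
    """
    docs = {d.doc_id: d for d in corpus}
    counts: dict[SectionType, int] = {s: 0 for s in SectionType}
    for p in positive_preds:
        if p.call != 1:
            continue
        doc = docs.get(p.doc_id)
        if doc is None:
            continue
        for section in _co_mention_sections(doc, p.gene_id, p.disease_id):
            counts[section] += 1
    return counts


def section_overlap_rate(a: set, b: set) -> float | None:
    """|A∩B| / min(|A|, |B|); None when either set is empty."""
    if not a or not b:
        return None
    return len(a & b) / min(len(a), len(b))


def section_recall_breakdown(
    per_model_preds: dict[str, list[PredictionRecord]],
    corpus: list[Document],
    labels: list[RelationLabel],
) -> dict[str, dict[SectionType, float | None]]:
    """Recall per section per model over section-attributed associations.

    An annotated association (target 1.0) is attributed to every section
    with a co-mention sentence; sections with no attributed labels report
    None.
    """
    docs = {d.doc_id: d for d in corpus}
    attributed: dict[SectionType, set[Triple]] = {s: set() for s in SectionType}
    for l in labels:
        if l.gdp_target != 1.0 or l.doc_id not in docs:
            continue
        for section in _co_mention_sections(docs[l.doc_id], l.gene_id, l.disease_id):
            attributed[section].add(l.triple)
    out: dict[str, dict[SectionType, float | None]] = {}
    for name, preds in per_model_preds.items():
        positive = {p.triple for p in preds if p.call == 1}
        by_section: dict[SectionType, float | None] = {}
        for section, triples in attributed.items():
            if not triples:
                by_section[section] = None
            else:
                by_section[section] = len(triples & positive) / len(triples)
        out[name] = by_section
    return out
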