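"""Iterative training-data-expansion bookkeeping.

One expansion iteration: (1) the current ensemble predicts over a corpus;
(2) positive calls are exported as a curation queue for manual review
(associated / ambiguous / non-associated); (3) negative calls that every
external method also calls negative become silver labels (inferred
non-associations, target 0); (4) gold + silver labels are assembled into
the next iteration's training set with a lineage manifest.  Stopping is a
human decision; the manifest records per-iteration statistics to support
it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .corpus_io import Document, PredictionRecord, RelationLabel
from .preprocess import EntityClass, SentencizedDocument, split_sentences

logger = logging.getLogger(__name__)

__all__ = [
    "export_curation_queue",
    "import_curated_labels",
    "build_silver_dataset",
    "assemble_iteration_training_set",
    "co_occurrence_predictor",
]

QUEUE_COLUMNS = ["doc_id", "gene_id", "disease_id", "mean_gdp", "snippet", "status"]
_STATUS_TO_TARGET = {"associated": 1.0, "ambiguous": 0.5, "non_associated": 0.0}
SNIPPET_SEPARATOR = " ||| "


def _sentence_text(sdoc: SentencizedDocument, idx: int) -> str:
    return " ".join(sdoc.sentences[idx])


def _sentence_entities(sdoc: SentencizedDocument, idx: int) -> set[tuple[EntityClass, str]]:
    return {r for r in sdoc.token_roles[idx] if r is not None}


def extract_snippet(sdoc: SentencizedDocument, gene_id: str, disease_id: str) -> str:
    """Supporting text for a curation row, deterministically chosen.

    First sentence containing both target entities; if they never
    co-occur, the first sentence containing each, concatenated with a
    separator.
    """
    g_key = (EntityClass.GENE, gene_id)
    d_key = (EntityClass.DISEASE, disease_id)
    first_g = first_d = None
    for i in range(len(sdoc.sentences)):
        ents = _sentence_entities(sdoc, i)
        if g_key in ents and d_key in ents:
            return _sentence_text(sdoc, i)
        if first_g is None and g_key in ents:
            first_g = i
        if first_d is None and d_key in ents:
            first_d = i
    parts = [
        _sentence_text(sdoc, i) for i in (first_g, first_d) if i is not None
    ]
    return SNIPPET_SEPARATOR.join(parts)


def export_curation_queue(
    preds: list[PredictionRecord],
    corpus: list[Document],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per positive ensemble call, sorted by descending mean GDP.

    Rows start with status ``pending``; the TSV is meant to be resolved in
    a spreadsheet and read back with :func:`import_curated_labels`.
    """
    sdocs = {doc.doc_id: None for doc in corpus}
    docs = {doc.doc_id: doc for doc in corpus}
    rows = []
    for r in preds:
        if r.call != 1:
            continue
        if r.doc_id not in docs:
            raise ValueError(f"prediction for unknown document {r.doc_id}")
        if sdocs[r.doc_id] is None:
            sdocs[r.doc_id] = split_sentences(docs[r.doc_id])
        rows.append(
            {
                "doc_id": r.doc_id,
                "gene_id": r.gene_id,
                "disease_id": r.disease_id,
                "mean_gdp": r.gdp_score,
                "snippet": extract_snippet(sdocs[r.doc_id], r.gene_id, r.disease_id),
                "status": "pending",
            }
        )
    df = pd.DataFrame(rows, columns=QUEUE_COLUMNS)
    df = df.sort_values(
        ["mean_gdp", "doc_id", "gene_id", "disease_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def import_curated_labels(
    queue: pd.DataFrame | str | Path, allow_partial: bool = False
) -> list[RelationLabel]:
    """Resolved curation rows as gold labels (1.0 / 0.5 / 0.0)."""
    df = queue if isinstance(queue, pd.DataFrame) else pd.read_csv(queue, sep="\t", dtype=str)
    labels: list[RelationLabel] = []
    for row in df.itertuples(index=False):
        status = str(row.status)
        if status == "pending":
            if allow_partial:
                continue
            raise ValueError(
                f"pending row ({row.doc_id}, {row.gene_id}, {row.disease_id}); "
                "resolve it or pass allow_partial"
            )
        if status not in _STATUS_TO_TARGET:
            raise ValueError(f"unknown curation status {status!r}")
        labels.append(
            RelationLabel(
                doc_id=str(row.doc_id),
                gene_id=str(row.gene_id),
                disease_id=str(row.disease_id),
                gdp_target=_STATUS_TO_TARGET[status],
                provenance="gold",
            )
        )
    return labels


def build_silver_dataset(
    own_preds: list[PredictionRecord],
    external_preds: list[PredictionRecord],
    universe: list[tuple[str, str, str]],
    gold_labels: list[RelationLabel] | None = None,
) -> list[RelationLabel]:
    """Inferred non-associations: negative by this tool and by every method.

    ``universe`` enumerates the (doc, gene, disease) triples under
    consideration.  A triple absent from a method's predictions counts as
    a negative call for that method (logged).  Triples carrying a gold
    label are never silver.
    """
    methods = sorted({r.method for r in external_preds})
    if not methods:
        raise ValueError("at least one external method is required")
    own_calls = {r.triple: r.call for r in own_preds}
    ext_calls: dict[str, dict[tuple[str, str, str], int]] = {m: {} for m in methods}
    for r in external_preds:
        ext_calls[r.method][r.triple] = r.call
    gold_triples = {l.triple for l in gold_labels} if gold_labels else set()

    n_missing = 0
    silver: list[RelationLabel] = []
    for triple in universe:
        if triple in gold_triples:
            continue
        if own_calls.get(triple, 0) != 0:
            continue
        unanimous = True
        for m in methods:
            if triple not in ext_calls[m]:
                n_missing += 1
            if ext_calls[m].get(triple, 0) != 0:
                unanimous = False
                break
        if unanimous:
            silver.append(RelationLabel(*triple, gdp_target=0.0, provenance="silver"))
    if n_missing:
        logger.info(
            "silver mining: %d (triple, method) pairs absent from prediction "
            "files were counted as negative calls",
            n_missing,
        )
    return silver


def co_occurrence_predictor(
    corpus: list[Document],
    method: str,
    min_sentence_cooccurrences: int = 1,
    require_sections=None,
) -> list[PredictionRecord]:
    """A rule-based stand-in for an external relation-extraction method.

    Calls a pair associated iff its entities co-occur in at least
    ``min_sentence_cooccurrences`` sentences (optionally restricted to
    ``require_sections``).  Real baselines are consumed as prediction
    files; this scorer exists so silver-set mining and the composite
    precision rule are testable without them.
    """
    from .preprocess import enumerate_candidate_pairs

    records: list[PredictionRecord] = []
    for doc in corpus:
        sdoc = split_sentences(doc)
        for gene_id, disease_id in enumerate_candidate_pairs(doc):
            n = 0
            for roles, section in zip(sdoc.token_roles, sdoc.sentence_section):
                if require_sections is not None and section not in require_sections:
                    continue
                ents = {r for r in roles if r is not None}
                if (EntityClass.GENE, gene_id) in ents and (
                    EntityClass.DISEASE,
                    disease_id,
                ) in ents:
                    n += 1
            call = int(n >= min_sentence_cooccurrences)
            records.append(
                PredictionRecord(
                    doc_id=doc.doc_id,
                    gene_id=gene_id,
                    disease_id=disease_id,
                    gdp_score=float(call),
                    call=call,
                    method=method,
                )
            )
    return records


def assemble_iteration_training_set(
    gold: list[RelationLabel],
    silver: list[RelationLabel],
    iteration_id: str,
    parent_iteration: str | None = None,
    validation_f1: float | None = None,
) -> tuple[list[RelationLabel], dict]:
    """Merge gold and silver labels; error on overlapping triples.

    Returns the merged label list plus a manifest recording provenance
    counts and iteration lineage.
    """
    overlap = {l.triple for l in gold} & {l.triple for l in silver}
    if overlap:
        listing = ", ".join(map(str, sorted(overlap)[:10]))
        raise ValueError(f"gold and silver labels overlap on triples: {listing}")
    merged = list(gold) + list(silver)
    manifest = {
        "iteration_id": iteration_id,
        "parent_iteration": parent_iteration,
        "counts": {"gold": len(gold), "silver": len(silver), "total": len(merged)},
        "validation_f1": validation_f1,
    }
    return merged, manifest
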