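"""Reading, validating and writing annotated full-text corpora.

The corpus container mirrors PubTator Central exports: a document is an
ordered list of passages (title, abstract and, for full text, one passage
per paragraph carrying a standardized section-type identifier) plus a flat
list of gene/disease mentions with document-global character spans and
normalized concept identifiers (Entrez gene IDs, MeSH disease IDs).

Relation labels attach a gene-disease association probability (GDP) target
to a (document, gene, disease) triple: 1.0 for an asserted association,
0.5 for an ambiguous one, 0.0 for a non-association.  Prediction tables
from external relation-extraction methods are consumed as flat TSV files.

Text dialect
------------
``parse_pubtator_docs`` / ``serialize_pubtator_docs`` speak two dialects:

* ``abstract``: classic two-line records ``docid|t|title`` and
  ``docid|a|abstract``.
* ``full_text``: one line per passage, ``docid|SECTION#k|text`` where
  ``SECTION`` is a section-type identifier and ``k`` the paragraph index
  within that section.

Annotation lines are tab-separated in both dialects::

    docid<TAB>start<TAB>end<TAB>surface<TAB>Gene|Disease<TAB>concept_id

with 0-based, half-open, document-global offsets.  The document text is
the concatenation of the passage texts in passage order, with no implicit
separator.  A blank line terminates each document record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SectionType",
    "EntityClass",
    "EntityMention",
    "Passage",
    "Document",
    "RelationLabel",
    "PredictionRecord",
    "CorpusError",
    "ParseError",
    "ValidationError",
    "parse_pubtator_docs",
    "serialize_pubtator_docs",
    "read_label_table",
    "write_label_table",
    "read_external_predictions",
    "write_prediction_table",
    "validate_document",
]


class CorpusError(Exception):
    """Base class for corpus-level errors."""


class ParseError(CorpusError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CorpusError):
    """A document or table violates a structural invariant."""


class SectionType(str, Enum):
    """Standardized section-type identifiers for full-text passages."""

    TITLE = "TITLE"
    ABSTRACT = "ABSTRACT"
    INTRO = "INTRO"
    METHODS = "METHODS"
    RESULTS = "RESULTS"
    DISCUSS = "DISCUSS"
    CONCL = "CONCL"
    CASE = "CASE"
    TABLE = "TABLE"
    FIG = "FIG"
    SUPPL = "SUPPL"
    REF = "REF"
    OTHER = "OTHER"

    @classmethod
    def coerce(cls, value: str) -> "SectionType":
        """Map a section-identifier string to the enum; unknown -> OTHER."""
        try:
            return cls(value.upper())
        except ValueError:
            logger.warning("unknown section type %r mapped to OTHER", value)
            return cls.OTHER


class EntityClass(str, Enum):
    GENE = "Gene"
    DISEASE = "Disease"


@dataclass(frozen=True)
class EntityMention:
    """One entity occurrence: [start, end) into the document text."""

    start: int
    end: int
    surface: str
    entity_class: EntityClass
    concept_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"mention span [{self.start}, {self.end}) is empty")
        if not self.concept_id:
            raise ValidationError("mention concept_id must be non-empty")


@dataclass(frozen=True)
class Passage:
    section_type: SectionType
    paragraph_index: int
    offset: int
    text: str

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


@dataclass
class Document:
    doc_id: str
    passages: list[Passage] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)

    @property
    def text(self) -> str:
        return "".join(p.text for p in self.passages)

    def mentions_of(self, entity_class: EntityClass) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_class is entity_class]

    def passage_of(self, mention: EntityMention) -> Passage | None:
        """The unique passage wholly containing the mention span, if any."""
        for p in self.passages:
            if p.offset <= mention.start and mention.end <= p.end:
                return p
        return None

    def mentions_in_passage(self, passage: Passage) -> list[EntityMention]:
        return [
            m
            for m in self.mentions
            if passage.offset <= m.start and m.end <= passage.end
        ]


@dataclass(frozen=True)
class RelationLabel:
    """A (doc, gene, disease) triple with its GDP training target.

    Targets live on the {0, 0.5, 1} lattice: 0 non-associated, 0.5
    ambiguous, 1 associated.  Silver labels (inferred non-associations
    cross-validated by several methods) are always 0.
    """

    doc_id: str
    gene_id: str
    disease_id: str
    gdp_target: float
    provenance: str = "gold"

    VALID_TARGETS = (0.0, 0.5, 1.0)

    def __post_init__(self) -> None:
        if self.gdp_target not in self.VALID_TARGETS:
            raise ValidationError(
                f"gdp_target must be one of {self.VALID_TARGETS}, got {self.gdp_target}"
            )
        if self.provenance not in ("gold", "silver"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "silver" and self.gdp_target != 0.0:
            raise ValidationError("silver labels must have gdp_target = 0.0")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.gene_id, self.disease_id)


@dataclass(frozen=True)
class PredictionRecord:
    """A scored (doc, gene, disease) pair from some relation-extraction method."""

    doc_id: str
    gene_id: str
    disease_id: str
    gdp_score: float
    call: int
    method: str = "renet-ft"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gdp_score <= 1.0:
            raise ValidationError(f"gdp_score {self.gdp_score} outside [0, 1]")
        if self.call not in (0, 1):
            raise ValidationError(f"call must be 0 or 1, got {self.call}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.doc_id, self.gene_id, self.disease_id)


# ---------------------------------------------------------------------------
# PubTator-style corpus files
# ---------------------------------------------------------------------------


def _parse_passage_tag(tag: str, lineno: int) -> tuple[SectionType, int]:
    if tag == "t":
        return SectionType.TITLE, 0
    if tag == "a":
        return SectionType.ABSTRACT, 0
    if "#" in tag:
        sec, _, idx = tag.partition("#")
        try:
            return SectionType.coerce(sec), int(idx)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad paragraph index in tag {tag!r}") from exc
    raise ParseError(f"line {lineno}: unrecognized passage tag {tag!r}")


def _passage_tag(passage: Passage, dialect: str) -> str:
    if dialect == "abstract":
        if passage.section_type is SectionType.TITLE:
            return "t"
        if passage.section_type is SectionType.ABSTRACT:
            return "a"
        raise ValidationError(
            f"abstract dialect cannot carry section {passage.section_type.value}"
        )
    return f"{passage.section_type.value}#{passage.paragraph_index}"


def _finish_document(
    doc_id: str,
    passages: list[Passage],
    raw_mentions: list[tuple[int, int, str, str, str]],
) -> Document:
    doc = Document(doc_id=doc_id, passages=passages)
    text = doc.text
    mentions = []
    for start, end, surface, ecls, cid in raw_mentions:
        if text[start:end] != surface:
            raise ValidationError(
                f"doc {doc_id}: annotation surface {surface!r} != document text "
                f"{text[start:end]!r} at [{start}, {end})"
            )
        mentions.append(
            EntityMention(
                start=start,
                end=end,
                surface=surface,
                entity_class=EntityClass(ecls),
                concept_id=cid,
            )
        )
    doc.mentions = mentions
    violations = validate_document(doc)
    if violations:
        raise ValidationError(f"doc {doc_id}: " + "; ".join(violations))
    return doc


def parse_pubtator_docs(path: str | Path, dialect: str = "full_text") -> list[Document]:
    """Parse a PubTator-style corpus file into validated documents.

    Parameters
    ----------
    path
        File to read (UTF-8).
    dialect
        ``"abstract"`` for classic title/abstract records, ``"full_text"``
        for per-passage section-tagged records.
    """
    if dialect not in ("abstract", "full_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    docs: list[Document] = []
    cur_id: str | None = None
    passages: list[Passage] = []
    raw_mentions: list[tuple[int, int, str, str, str]] = []
    offset = 0

    def flush() -> None:
        nonlocal cur_id, passages, raw_mentions, offset
        if cur_id is not None:
            docs.append(_finish_document(cur_id, passages, raw_mentions))
        cur_id, passages, raw_mentions, offset = None, [], [], 0

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                flush()
                continue
            if "\t" in line:
                fields = line.split("\t")
                if len(fields) != 6:
                    raise ParseError(
                        f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                    )
                doc_id, start_s, end_s, surface, ecls, cid = fields
                if doc_id != cur_id:
                    raise ParseError(
                        f"line {lineno}: annotation for {doc_id!r} outside its document"
                    )
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-integer span") from exc
                if ecls not in (EntityClass.GENE.value, EntityClass.DISEASE.value):
                    raise ParseError(f"line {lineno}: unknown entity class {ecls!r}")
                raw_mentions.append((start, end, surface, ecls, cid))
            elif "|" in line:
                doc_id, _, rest = line.partition("|")
                tag, _, text = rest.partition("|")
                if not doc_id or not tag:
                    raise ParseError(f"line {lineno}: malformed passage line")
                if cur_id is not None and doc_id != cur_id:
                    flush()
                if cur_id is None:
                    cur_id = doc_id
                section, par_idx = _parse_passage_tag(tag, lineno)
                if dialect == "abstract" and tag not in ("t", "a"):
                    raise ParseError(
                        f"line {lineno}: abstract dialect allows only t/a passages"
                    )
                if dialect == "full_text" and tag in ("t", "a"):
                    # tolerated: t/a map to TITLE/ABSTRACT paragraph 0
                    pass
                passages.append(
                    Passage(
                        section_type=section,
                        paragraph_index=par_idx,
                        offset=offset,
                        text=text,
                    )
                )
                offset += len(text)
            else:
                raise ParseError(f"line {lineno}: unrecognized line {line!r}")
    flush()
    return docs


def serialize_pubtator_docs(
    docs: Sequence[Document], path: str | Path, dialect: str = "full_text"
) -> None:
    """Write documents in the dialect ``parse_pubtator_docs`` accepts.

    Passage offsets are recomputed from the passage order; output is
    byte-stable for identical input.
    """
    if dialect not in ("abstract", "full_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            for passage in doc.passages:
                fh.write(f"{doc.doc_id}|{_passage_tag(passage, dialect)}|{passage.text}\n")
            for m in doc.mentions:
                fh.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}"
                    f"\t{m.entity_class.value}\t{m.concept_id}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Label and prediction tables
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ["doc_id", "gene_id", "disease_id", "gdp_target"]


def read_label_table(path: str | Path) -> list[RelationLabel]:
    """Read a TSV relation-label table; rejects bad targets and duplicates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"label table missing columns {missing}")
    labels: list[RelationLabel] = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        try:
            target = float(row.gdp_target)
        except ValueError as exc:
            raise ValidationError(f"non-numeric gdp_target {row.gdp_target!r}") from exc
        provenance = getattr(row, "provenance", "gold")
        if provenance is None or pd.isna(provenance):
            provenance = "gold"
        label = RelationLabel(
            doc_id=str(row.doc_id),
            gene_id=str(row.gene_id),
            disease_id=str(row.disease_id),
            gdp_target=target,
            provenance=str(provenance),
        )
        if label.triple in seen:
            raise ValidationError(f"duplicate label triple {label.triple}")
        seen.add(label.triple)
        labels.append(label)
    return labels


def write_label_table(labels: Iterable[RelationLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "doc_id": l.doc_id,
                "gene_id": l.gene_id,
                "disease_id": l.disease_id,
                "gdp_target": l.gdp_target,
                "provenance": l.provenance,
            }
            for l in labels
        ],
        columns=_LABEL_COLUMNS + ["provenance"],
    )
    df.to_csv(path, sep="\t", index=False)


_PRED_COLUMNS = ["doc_id", "gene_id", "disease_id", "call"]


def read_external_predictions(
    paths: Sequence[str | Path], method_tags: Sequence[str]
) -> list[PredictionRecord]:
    """Read one binary-call prediction TSV per external method.

    A pair absent from a method's file is interpreted as call = 0 by
    downstream consumers (silver-set construction, composite precision);
    the reader itself only materializes the rows that are present.
    """
    if len(paths) != len(method_tags):
        raise ValueError("paths and method_tags must have equal length")
    records: list[PredictionRecord] = []
    for path, tag in zip(paths, method_tags):
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.empty and not set(_PRED_COLUMNS) <= set(df.columns):
            continue
        missing = [c for c in _PRED_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: prediction table missing columns {missing}")
        for row in df.itertuples(index=False):
            score = getattr(row, "gdp_score", None)
            call = int(row.call)
            records.append(
                PredictionRecord(
                    doc_id=str(row.doc_id),
                    gene_id=str(row.gene_id),
                    disease_id=str(row.disease_id),
                    gdp_score=float(score) if score is not None and not pd.isna(score) else float(call),
                    call=call,
                    method=tag,
                )
            )
    return records


def write_prediction_table(
    records: Iterable[PredictionRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "doc_id": r.doc_id,
                "gene_id": r.gene_id,
                "disease_id": r.disease_id,
                "gdp_score": r.gdp_score,
                "call": r.call,
                "method": r.method,
            }
            for r in records
        ],
        columns=_PRED_COLUMNS[:3] + ["gdp_score", "call", "method"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_document(doc: Document) -> list[str]:
    """Check all structural invariants; returns human-readable violations.

    An empty list means the document is valid.  Violations name the
    document, the field and the rule; nothing is raised.
    """
    violations: list[str] = []
    expected_offset = 0
    for i, p in enumerate(doc.passages):
        if p.offset != expected_offset:
            violations.append(
                f"doc {doc.doc_id}: passage {i} offset {p.offset} != expected "
                f"{expected_offset} (passages must tile the document)"
            )
        expected_offset = p.offset + len(p.text)
    text = doc.text
    for m in doc.mentions:
        if m.end > len(text):
            violations.append(
                f"doc {doc.doc_id}: mention span [{m.start}, {m.end}) beyond "
                f"document end {len(text)}"
            )
            continue
        containing = [
            p for p in doc.passages if p.offset <= m.start and m.end <= p.end
        ]
        if len(containing) != 1:
            violations.append(
                f"doc {doc.doc_id}: mention {m.surface!r} at [{m.start}, {m.end}) "
                f"lies inside {len(containing)} passages (expected exactly 1)"
            )
        if text[m.start : m.end] != m.surface:
            violations.append(
                f"doc {doc.doc_id}: mention surface {m.surface!r} != text "
                f"{text[m.start:m.end]!r} at [{m.start}, {m.end})"
            )
    return violations


def rebuild_document(
    doc_id: str,
    kept_passages: Sequence[Passage],
    mentions: Sequence[EntityMention],
) -> Document:
    """Re-tile passages from offset 0 and shift mention spans accordingly.

    ``mentions`` must lie inside ``kept_passages`` (spans given in the old
    coordinate system); mentions outside any kept passage are dropped.
    Used by the section-filtering and section-exclusion transforms.
    """
    new_passages: list[Passage] = []
    shift: list[tuple[int, int, int]] = []  # (old_start, old_end, delta)
    offset = 0
    for p in kept_passages:
        shift.append((p.offset, p.end, offset - p.offset))
        new_passages.append(replace(p, offset=offset))
        offset += len(p.text)
    new_mentions: list[EntityMention] = []
    for m in mentions:
        for old_start, old_end, delta in shift:
            if old_start <= m.start and m.end <= old_end:
                new_mentions.append(replace(m, start=m.start + delta, end=m.end + delta))
                break
    return Document(doc_id=doc_id, passages=new_passages, mentions=new_mentions)
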