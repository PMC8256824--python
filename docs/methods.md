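# Methods

## Problem and data model

The unit of analysis is one full-text article with upstream named-entity
annotations: an ordered list of passages carrying standardized
section-type identifiers (TITLE, ABSTRACT, INTRO, METHODS, RESULTS,
DISCUSS, …) and a list of gene/disease mentions with 0-based, half-open,
document-global character spans and normalized concept IDs (Entrez gene,
MeSH disease). Pair identity is by concept ID, never by surface string;
concept IDs are treated as opaque (entity normalization is out of
scope). Overlapping or nested mentions are retained as given; when a
token is covered by both a gene and a disease mention, the gene role
wins deterministically and the conflict is logged.

The text dialect is declared rather than inferred: passage lines
`docid|SECTION#k|text` (or `t`/`a` in the abstract dialect), annotation
lines `docid<TAB>start<TAB>end<TAB>surface<TAB>Gene|Disease<TAB>id`,
blank-line record separation, document text equal to the concatenation
of passage texts with no implicit separator. Unknown section identifiers
map to OTHER with a warning, since section vocabularies drift.

## Preprocessing

**Sentence splitting and tokenization** are rule-based and span-safe:
tokens are maximal word-character runs or single punctuation marks, with
boundaries forced at mention span edges so roles align exactly with
tokens; sentences end at `. ! ?` outside mention spans (small
abbreviation guard list) and are always forced closed at passage
boundaries. This is deterministic and dependency-light; no statistical
sentence model is used.

**Section Filtering (SeFi)** keeps a paragraph iff it contains at least
one gene mention *and* one disease mention. Titles are exempt (they are
not paragraphs). SeFi is applied at both training and prediction time —
it is a preprocessing step — and is flag-controllable. METHODS passages
are additionally dropped at training time only; prediction never drops
sections by default.

**Encoding.** For each candidate pair (the Cartesian product of the
unique gene and disease concept IDs present after filtering, in
lexicographic order) the document becomes two S×T integer grids: token
indices into a frequency-thresholded vocabulary (index 0 padding, 1
unknown; ties broken by frequency then lexicographic order) and role
symbols {0 none, 1 target gene, 2 target disease, 3 non-target gene, 4
non-target disease}. Limits are T = 54 tokens per sentence and S = 1000
sentences (54 000 tokens of capacity); truncation keeps the earliest
sentences and tokens, because the informative sections (title, abstract,
introduction) come first.

## Network and training

Word vectors (trained from scratch; no external embeddings, so no
downloads) are concatenated with a 4-dimensional one-hot role feature
(role 0 is the zero vector). Sentence representation: parallel 1-D
convolutions of widths {2,3,4,5} × 64 channels, ReLU, max-pooling over
valid window positions (windows that would cover padding are masked;
a sentence shorter than a width contributes zeros for that width).
Document representation: a single-layer GRU over the sentence vectors
in document order, with padded sentence steps masked so batch
composition cannot affect a document's score. Head: 128 → 64 → 1 with
ReLU, dropout and a final sigmoid, giving the gene–disease association
probability (GDP) strictly inside (0, 1).

Targets live on {0, 0.5, 1}: 0.5 encodes an *ambiguous* association
(hedged by the authors, or undecidable by a curator) and is used in
training only — evaluation operates on associated/non-associated. The
loss is the per-article mean squared error over the n×m pair grid;
batches are formed at document granularity (default 8 documents) and
average the squared error over all pairs in the batch, which keeps the
scale of the gradient stable across articles of different sizes. Only
labeled pairs contribute to the loss; unlabeled pairs are never assumed
non-associated. Documents with no candidate pairs are skipped with a
log line. The optimizer is Adam with fixed seed; the reproducibility
contract is identical metrics under identical seed/config/data on one
device, not cross-device bitwise equality.

The published description defers exact hyperparameters to external
material, so the defaults here (embedding 100, 4×64 CNN, GRU 128, head
64, dropout 0.5, lr 1e-3, 10 epochs, batch 8 documents) are this
package's own reconstruction, all configurable. `ModelConfig.small()`
(embedding 24, widths {2,3} × 12 channels, GRU 24, head 16, dropout
0.2, lr 3e-3, 6 epochs) is the configuration used for the CPU-scale
benchmarks in the test suite and acceptance script.

The network runs on a minimal in-repo reverse-mode autodiff engine over
numpy supporting exactly the required operations; its gradients are
checked against central finite differences in the test suite. The
max-pool subgradient follows the argmax (first occurrence on ties, via
`argmax`), which is the conventional choice.

Prediction binarizes the GDP with a strict threshold: associated iff
p̂ > 0.5, so p̂ = 0.5 is non-associated.

## Ensembling

θ = 10 models differing only by seed vote with their binary calls. The
default rule is non-strict majority, Σŷₖ ≥ θ/2, implemented in integer
arithmetic (2Σ ≥ θ) to avoid floating-point ties: 5 of 10 votes is
positive. The high-sensitivity mode changes exactly two things: silver
labels are excluded from training, and one positive member vote
suffices. Votes are calls, not averaged scores; the mean GDP is
reported for ranking only. Any-positive voting dominates majority
voting pointwise, so high-sensitivity recall is ≥ default recall by
construction — the test suite asserts it on actual predictions as well.

## Training-data expansion

Positive ensemble calls are exported as a curation queue (sorted by
descending mean GDP; supporting snippet = first sentence co-mentioning
the pair, else the first sentence containing each entity joined by a
separator). Curators resolve each row to associated (1.0), ambiguous
(0.5) or non-associated (0.0); resolved rows become gold labels —
including ensemble positives curated negative, which enter as hard
negatives. Negative calls unanimously confirmed by every external
method become silver labels (target 0); a pair absent from a method's
file counts as a negative call for that method, logged. External
methods are consumed strictly as prediction files; for testing, the
package ships a rule-based sentence co-occurrence scorer as a mocked
external method. Gold and silver must be disjoint; assembly errors on
overlap and writes a manifest with provenance counts and lineage.
Stopping the iteration is a human decision; no automatic rule is
imposed.

## Evaluation

Full-text corpora are not exhaustively annotated, so precision uses the
composite rule: a positive prediction is TP iff (i) the pair carries an
associated (1.0) validation label, or (ii) every supplied method calls
it associated; otherwise FP, with an audit trail of which clause fired.
Clause (i) is interpreted as a positive prediction matching an
associated label (not a matching negative). Positive predictions on
ambiguous-labeled pairs are excluded from both TP and FP. Recall is
(annotated associations correctly predicted)/(annotated associations);
ambiguous labels are excluded from the denominator. Undefined ratios
are reported as NA, never coerced to 0.

Cross-validation defaults to a seeded 5-fold document-level partition
(fold sizes differ by at most one); a `resample` scheme of 5
independent 80/20 draws is available where the literal reading of
"randomly picked 80%/20%" is wanted.

Section analyses attribute an association to every section containing
at least one sentence that co-mentions both target entities — the
weakest defensible attribution signal, stated explicitly because no
canonical definition exists. The overlap rate between the association
sets of two sections is |A∩B| / min(|A|, |B|) (NA when either set is
empty).

## Synthetic corpus

The generator emulates the annotated full-text setting end to end:
section-tagged paragraphs, entity mentions with spans and synthetic
concept IDs (`GENE:<int>`, `MESH:D<int>`, with single- and multi-token
surfaces to exercise span bookkeeping), and complete truth labels —
every (gene, disease) pair of a document is labeled, so
|labels| = #genes × #diseases. Associated pairs receive 1–2 assertive
trigger sentences, ambiguous pairs only hedged triggers, non-associated
pairs only trigger-free co-mentions split across sentences; METHODS
noise paragraphs contain no entities at all. "Hard mode" adds
single-sentence co-mentions of non-associated pairs without triggers,
so co-occurrence alone cannot separate the classes. Defaults: 1–2 genes
and diseases per document, P(associated) = 0.35, P(ambiguous) = 0.15,
noise-paragraph rate 0.5 — a density in the range of annotated
abstracts, kept small enough that a complete truth labeling is
plausible. Generation is byte-identical under a fixed seed.

What the generator does *not* emulate: linguistic variety, negation
scope, coreference, abbreviations, entity sharing across documents
(concept IDs are document-unique, so corpus-level deduplication
percentages are trivially 100% and that statistic is exercised through
printed-count worked examples instead), and annotation noise. Passing
the label-recovery benchmark therefore shows that the pipeline learns
document-level trigger/context patterns and that its bookkeeping is
correct — not that it reaches any particular accuracy on real
literature.

## Benchmark problem sizes

The label-recovery benchmark uses 300 training / 100 test documents
(~900 candidate pairs), `ModelConfig.small()`, and a 10-member
ensemble; these sizes are the package's standard configuration for the
benchmark and complete in a few minutes on one CPU. The worked metric
examples recompute F1 values and deltas from published
precision/recall tables at the precision those tables print. Two
printed increments (4.19% and 8.32%) and the printed precision margins
of the method-comparison table are not reproducible from the printed
F1/precision values themselves (they were evidently computed from
unrounded values); only the self-consistent ones are recomputed. The
published abstract-corpus unique-pair percentage prints 91.2%, but the
printed counts give 2568/2813 = 91.29% → 91.3 under round-half-up; the
computed value is reported.

## Known limitations

* One pair is encoded and scored at a time; pairs of the same document
  share no computation.
* The autodiff engine is adequate for the reduced-size configurations
  exercised here; the full-size default configuration trains but is
  slow on one CPU.
* The splitter's abbreviation guard is a short fixed list; exotic
  abbreviation patterns will over-split sentences (harmless for role
  alignment, which never crosses mention spans).
* No statistical significance testing or bootstrap intervals on the
  evaluation metrics.
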