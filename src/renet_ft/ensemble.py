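"""Seeded model ensembles with majority or any-positive voting.

The default mode trains theta (default 10) networks that differ only by
seed and calls a pair associated when at least half of the members do
(the inequality is non-strict: 5 of 10 votes is positive).  The
high-sensitivity mode favors recall: silver (inferred-negative) labels
are excluded from training and a single positive member vote suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import PredictionRecord, RelationLabel
from .model import GDPModel, ModelConfig, build_model, train_model
from .preprocess import EncodedInstance

logger = logging.getLogger(__name__)

__all__ = ["EnsembleConfig", "train_ensemble", "ensemble_vote", "ensemble_predict"]

DEFAULT_MODE = "default"
HIGH_SENSITIVITY_MODE = "high_sensitivity"


@dataclass(frozen=True)
class EnsembleConfig:
    theta: int = 10
    mode: str = DEFAULT_MODE
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.mode not in (DEFAULT_MODE, HIGH_SENSITIVITY_MODE):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        seeds = self.seeds or tuple(range(self.theta))
        if len(seeds) != self.theta:
            raise ValueError(f"expected {self.theta} seeds, got {len(seeds)}")
        if len(set(seeds)) != len(seeds):
            raise ValueError("ensemble seeds must be distinct")
        object.__setattr__(self, "seeds", tuple(seeds))


def train_ensemble(
    instances: list[EncodedInstance],
    labels: list[RelationLabel],
    model_config: ModelConfig,
    ens_config: EnsembleConfig,
    vocab_size: int,
) -> list[GDPModel]:
    """Train theta models differing only by seed.

    In high-sensitivity mode silver labels are excluded from training (and
    the instances they label are dropped); the exclusion is logged.
    """
    train_labels = list(labels)
    train_instances = list(instances)
    if ens_config.mode == HIGH_SENSITIVITY_MODE:
        silver = {l.triple for l in labels if l.provenance == "silver"}
        if silver:
            logger.info(
                "high-sensitivity mode: excluding %d silver labels from training",
                len(silver),
            )
            train_labels = [l for l in labels if l.provenance != "silver"]
            train_instances = [
                i for i in instances if (i.doc_id, *i.pair) not in silver
            ]
    models: list[GDPModel] = []
    for seed in ens_config.seeds:
        from dataclasses import replace

        cfg = replace(model_config, seed=seed)
        model = build_model(cfg, vocab_size, rng_seed=seed)
        train_model(model, train_instances, train_labels, cfg)
        models.append(model)
    return models


def ensemble_vote(calls: list[int] | np.ndarray, mode: str = DEFAULT_MODE, theta: int | None = None) -> int:
    """Combine theta binary member calls into one ensemble call.

    Default: positive iff at least half the members vote positive
    (integer arithmetic, ``2 * sum >= theta``, so ties are positive).
    High-sensitivity: positive iff any member votes positive.
    """
    calls = list(calls)
    if theta is not None and len(calls) != theta:
        raise ValueError(f"expected {theta} votes, got {len(calls)}")
    if not calls:
        raise ValueError("no votes supplied")
    if any(c not in (0, 1) for c in calls):
        raise ValueError("votes must be binary")
    s = sum(calls)
    if mode == HIGH_SENSITIVITY_MODE:
        return int(s >= 1)
    if mode != DEFAULT_MODE:
        raise ValueError(f"unknown ensemble mode {mode!r}")
    return int(2 * s >= len(calls))


def ensemble_predict(
    per_model_records: list[list[PredictionRecord]],
    mode: str = DEFAULT_MODE,
) -> list[PredictionRecord]:
    """Combine per-member prediction lists (aligned by position).

    The ensemble call votes on the members' binary calls; the reported
    score is the mean GDP across members (for ranking only, never for the
    call).
    """
    if not per_model_records:
        raise ValueError("no member predictions supplied")
    n = len(per_model_records[0])
    if any(len(r) != n for r in per_model_records):
        raise ValueError("member prediction lists differ in length")
    out: list[PredictionRecord] = []
    for i in range(n):
        row = [r[i] for r in per_model_records]
        triples = {r.triple for r in row}
        if len(triples) != 1:
            raise ValueError(f"member predictions misaligned at position {i}: {triples}")
        call = ensemble_vote([r.call for r in row], mode=mode)
        mean_gdp = float(np.mean([r.gdp_score for r in row]))
        out.append(
            PredictionRecord(
                doc_id=row[0].doc_id,
                gene_id=row[0].gene_id,
                disease_id=row[0].disease_id,
                gdp_score=mean_gdp,
                call=call,
                method=f"renet-ft-ensemble-{mode}",
            )
        )
    return out
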