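"""The gene-disease association network and its training loop.

Architecture: word embeddings concatenated with a 4-symbol one-hot role
vector (target gene / target disease / non-target gene / non-target
disease), a multi-width 1-D CNN with per-sentence max-pooling building
sentence representations, a gated recurrent unit (GRU) running over the
sentence sequence to build the document representation conditioned on the
candidate pair, and a feed-forward head whose sigmoid output is the
gene-disease association probability (GDP) in (0, 1).

Training is regression: targets live on {0, 0.5, 1} (non-associated /
ambiguous / associated) and the loss is the mean squared error over the
candidate pairs of each article, averaged across the batch.  At
prediction time a pair is called associated iff its GDP is strictly
greater than 0.5.

The published description leaves the exact hyperparameters to external
material; the defaults below are this package's own reconstruction and
are all configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Adam, Tensor, concat, embedding
from .corpus_io import PredictionRecord, RelationLabel
from .preprocess import (
    MAX_SENTENCES,
    MAX_TOKENS_PER_SENTENCE,
    EncodedInstance,
    Vocabulary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "GDPModel",
    "build_model",
    "mse_loss",
    "train_model",
    "score_instances",
    "binarize_gdp",
]

N_ROLE_FEATURES = 4  # one-hot over roles 1..4; role 0 is the zero vector


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults are the package's reconstruction."""

    embedding_dim: int = 100
    cnn_filter_widths: tuple[int, ...] = (2, 3, 4, 5)
    cnn_channels: int = 64
    rnn_hidden_size: int = 128
    head_hidden_size: int = 64
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8  # documents per batch
    max_sentences: int = MAX_SENTENCES
    max_tokens_per_sentence: int = MAX_TOKENS_PER_SENTENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.cnn_channels, self.rnn_hidden_size,
               self.head_hidden_size, self.batch_size) <= 0:
            raise ValueError("all dimensions must be positive")
        if not self.cnn_filter_widths or min(self.cnn_filter_widths) < 1:
            raise ValueError("cnn_filter_widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """A reduced-size configuration for CPU-scale experiments."""
        defaults = dict(
            embedding_dim=24,
            cnn_filter_widths=(2, 3),
            cnn_channels=12,
            rnn_hidden_size=24,
            head_hidden_size=16,
            dropout_rate=0.2,
            learning_rate=3e-3,
            epochs=6,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def sentence_feature_dim(self) -> int:
        return self.cnn_channels * len(self.cnn_filter_widths)


class GDPModel:
    """Parameter store plus forward pass; see module docstring.

    Scoring is deterministic given fixed parameters and input; identical
    config + seed + data reproduce identical parameters on one device.
    """

    def __init__(self, config: ModelConfig, vocab_size: int, seed: int | None = None):
        if vocab_size < 2:
            raise ValueError("vocab_size must be >= 2 (padding + unknown)")
        self.config = config
        self.vocab_size = vocab_size
        self.vocab_fingerprint: str | None = None
        self.vocabulary: Vocabulary | None = None
        self.history: list[float] = []
        rng = np.random.default_rng(config.seed if seed is None else seed)
        d_in = config.embedding_dim + N_ROLE_FEATURES
        F = config.sentence_feature_dim
        H = config.rnn_hidden_size

        def glorot(fan_in: int, fan_out: int, shape) -> np.ndarray:
            a = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-a, a, size=shape)

        p: dict[str, Tensor] = {}
        emb = rng.normal(0.0, 0.1, size=(vocab_size, config.embedding_dim))
        emb[0] = 0.0  # padding row
        p["embedding"] = Tensor(emb, requires_grad=True)
        for w in config.cnn_filter_widths:
            p[f"conv{w}_W"] = Tensor(glorot(w * d_in, config.cnn_channels,
                                            (w * d_in, config.cnn_channels)), requires_grad=True)
            p[f"conv{w}_b"] = Tensor(np.zeros(config.cnn_channels), requires_grad=True)
        for gate in ("z", "r", "c"):
            p[f"gru_W{gate}"] = Tensor(glorot(F, H, (F, H)), requires_grad=True)
            p[f"gru_U{gate}"] = Tensor(glorot(H, H, (H, H)), requires_grad=True)
            p[f"gru_b{gate}"] = Tensor(np.zeros(H), requires_grad=True)
        p["head_W1"] = Tensor(glorot(H, config.head_hidden_size,
                                     (H, config.head_hidden_size)), requires_grad=True)
        p["head_b1"] = Tensor(np.zeros(config.head_hidden_size), requires_grad=True)
        p["head_W2"] = Tensor(glorot(config.head_hidden_size, 1,
                                     (config.head_hidden_size, 1)), requires_grad=True)
        p["head_b2"] = Tensor(np.zeros(1), requires_grad=True)
        self.params = p

    # -- bookkeeping --------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    @property
    def param_count(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def expected_param_count(self) -> int:
        """Closed-form parameter count implied by the configuration."""
        c = self.config
        d_in = c.embedding_dim + N_ROLE_FEATURES
        n = self.vocab_size * c.embedding_dim
        n += sum(w * d_in * c.cnn_channels + c.cnn_channels for w in c.cnn_filter_widths)
        F, H = c.sentence_feature_dim, c.rnn_hidden_size
        n += 3 * (F * H + H * H + H)
        n += H * c.head_hidden_size + c.head_hidden_size
        n += c.head_hidden_size * 1 + 1
        return n

    def bind_vocabulary(self, vocab: Vocabulary) -> None:
        if len(vocab) != self.vocab_size:
            raise ValueError(
                f"vocabulary size {len(vocab)} != model vocab_size {self.vocab_size}"
            )
        self.vocab_fingerprint = vocab.fingerprint
        self.vocabulary = vocab

    # -- forward ------------------------------------------------------------

    def _check_instances(self, instances: list[EncodedInstance]) -> None:
        c = self.config
        for inst in instances:
            S, T = inst.token_ids.shape
            if S > c.max_sentences or T != c.max_tokens_per_sentence:
                raise ValueError(
                    f"instance {inst.doc_id}/{inst.pair}: grid {S}x{T} exceeds "
                    f"capacity {c.max_sentences}x{c.max_tokens_per_sentence}"
                )
            if inst.token_ids.size and inst.token_ids.max() >= self.vocab_size:
                raise ValueError(
                    f"instance {inst.doc_id}/{inst.pair}: token index "
                    f"{int(inst.token_ids.max())} outside the model vocabulary "
                    f"(size {self.vocab_size}); vocabulary mismatch"
                )

    def forward(
        self,
        instances: list[EncodedInstance],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """GDP scores for a batch of encoded instances; shape (B, 1)."""
        self._check_instances(instances)
        c = self.config
        B = len(instances)
        if B == 0:
            raise ValueError("empty batch")
        T = c.max_tokens_per_sentence
        S_max = max(1, max(inst.n_sentences for inst in instances))
        ids = np.zeros((B, S_max, T), dtype=np.int64)
        roles = np.zeros((B, S_max, T), dtype=np.int64)
        lengths = np.zeros((B, S_max), dtype=np.int64)
        for b, inst in enumerate(instances):
            S = inst.n_sentences
            ids[b, :S] = inst.token_ids
            roles[b, :S] = inst.role_ids
            lengths[b, :S] = inst.valid_lengths

        BS = B * S_max
        flat_ids = ids.reshape(BS, T)
        flat_roles = roles.reshape(BS, T)
        flat_len = lengths.reshape(BS)

        x_word = embedding(self.params["embedding"], flat_ids)  # (BS, T, dw)
        role_onehot = np.zeros((BS, T, N_ROLE_FEATURES))
        for r in range(1, N_ROLE_FEATURES + 1):
            role_onehot[:, :, r - 1] = flat_roles == r
        x = concat([x_word, Tensor(role_onehot)], axis=2)  # (BS, T, d_in)

        pooled: list[Tensor] = []
        for w in c.cnn_filter_widths:
            K = T - w + 1
            windows = concat([x[:, i : i + K, :] for i in range(w)], axis=2)
            h = (windows @ self.params[f"conv{w}_W"] + self.params[f"conv{w}_b"]).relu()
            n_valid = np.maximum(flat_len - w + 1, 0)  # (BS,)
            valid = (np.arange(K)[None, :] < n_valid[:, None]).astype(float)
            h = h * valid[:, :, None] + (-1e9) * (1.0 - valid[:, :, None])
            m = h.max(axis=1)  # (BS, C)
            any_valid = (n_valid > 0).astype(float)[:, None]
            pooled.append(m * any_valid)
        sv = concat(pooled, axis=1)  # (BS, F)

        if train and c.dropout_rate > 0:
            if rng is None:
                raise ValueError("training forward pass requires an rng for dropout")
            keep = 1.0 - c.dropout_rate
            mask = rng.random(sv.shape) < keep
            sv = sv * (mask / keep)

        F = c.sentence_feature_dim
        sv = sv.reshape(B, S_max, F)
        sent_mask = (lengths > 0).astype(float)  # (B, S_max)

        H = c.rnn_hidden_size
        h_t = Tensor(np.zeros((B, H)))
        for t in range(S_max):
            x_t = sv[:, t, :]
            z = (x_t @ self.params["gru_Wz"] + h_t @ self.params["gru_Uz"] + self.params["gru_bz"]).sigmoid()
            r = (x_t @ self.params["gru_Wr"] + h_t @ self.params["gru_Ur"] + self.params["gru_br"]).sigmoid()
            cand = (x_t @ self.params["gru_Wc"] + (r * h_t) @ self.params["gru_Uc"] + self.params["gru_bc"]).tanh()
            h_new = (1.0 - z) * h_t + z * cand
            m_t = sent_mask[:, t : t + 1]
            h_t = h_new * m_t + h_t * (1.0 - m_t)

        u = (h_t @ self.params["head_W1"] + self.params["head_b1"]).relu()
        if train and c.dropout_rate > 0:
            keep = 1.0 - c.dropout_rate
            mask = rng.random(u.shape) < keep
            u = u * (mask / keep)
        return (u @ self.params["head_W2"] + self.params["head_b2"]).sigmoid()

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single self-describing archive: parameters + config + vocabulary tag."""
        meta = {
            "config": asdict(self.config),
            "vocab_size": self.vocab_size,
            "vocab_fingerprint": self.vocab_fingerprint,
            "vocab_tokens": (
                self.vocabulary.tokens_in_index_order if self.vocabulary else None
            ),
            "history": self.history,
        }
        arrays = {name: t.data for name, t in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "GDPModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            cfg = meta["config"]
            cfg["cnn_filter_widths"] = tuple(cfg["cnn_filter_widths"])
            config = ModelConfig(**cfg)
            model = cls(config, meta["vocab_size"])
            model.vocab_fingerprint = meta["vocab_fingerprint"]
            tokens = meta.get("vocab_tokens")
            if tokens is not None:
                model.vocabulary = Vocabulary({t: i + 2 for i, t in enumerate(tokens)})
            model.history = list(meta.get("history", []))
            for name in model.params:
                model.params[name] = Tensor(npz[name], requires_grad=True)
        return model


def build_model(config: ModelConfig, vocab_size: int, rng_seed: int | None = None) -> GDPModel:
    """An untrained network with seeded initialization."""
    return GDPModel(config, vocab_size, seed=rng_seed)


def mse_loss(predicted: np.ndarray, target: np.ndarray, n: int | None = None, m: int | None = None) -> float:
    """Per-article mean squared error over the n x m gene-disease pair grid."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    if n is not None and m is not None and predicted.shape != (n, m):
        raise ValueError(f"expected grid shape ({n}, {m}), got {predicted.shape}")
    return float(np.mean((predicted - target) ** 2))


def binarize_gdp(score: float) -> int:
    """Associated iff the GDP is strictly greater than 0.5."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"GDP score {score} outside [0, 1]")
    return int(score > 0.5)


def _labels_as_dict(labels) -> dict[tuple[str, str, str], float]:
    if isinstance(labels, dict):
        return labels
    return {l.triple: l.gdp_target for l in labels}


def train_model(
    model: GDPModel,
    instances: list[EncodedInstance],
    labels: list[RelationLabel] | dict[tuple[str, str, str], float],
    config: ModelConfig | None = None,
) -> GDPModel:
    """Fit the network in place by MSE against {0, 0.5, 1} targets.

    Batches are formed at document granularity; the loss of a batch is the
    squared error averaged over all its candidate pairs.  Deterministic
    under a fixed seed (shuffling and dropout come from one seeded
    generator); per-epoch mean training loss is logged and appended to
    ``model.history``.
    """
    c = config or model.config
    if not instances:
        raise ValueError("empty training set")
    lab = _labels_as_dict(labels)
    by_doc: dict[str, list[EncodedInstance]] = {}
    for inst in instances:
        triple = (inst.doc_id, *inst.pair)
        if triple not in lab:
            raise ValueError(f"instance {triple} has no training label")
        by_doc.setdefault(inst.doc_id, []).append(inst)
    doc_ids = sorted(by_doc)
    empty = [d for d in doc_ids if not by_doc[d]]
    for d in empty:  # pragma: no cover - defensive
        logger.info("document %s has no candidate pairs; skipped", d)
        doc_ids.remove(d)

    rng = np.random.default_rng(c.seed)
    opt = Adam(model.parameters(), lr=c.learning_rate)
    for epoch in range(c.epochs):
        order = rng.permutation(len(doc_ids))
        total_sq, total_n = 0.0, 0
        for start in range(0, len(order), c.batch_size):
            batch_docs = [doc_ids[i] for i in order[start : start + c.batch_size]]
            batch = [inst for d in batch_docs for inst in by_doc[d]]
            targets = np.array([[lab[(i.doc_id, *i.pair)]] for i in batch])
            opt.zero_grad()
            pred = model.forward(batch, train=True, rng=rng)
            diff = pred - Tensor(targets)
            loss = (diff * diff).mean()
            loss.backward()
            opt.step()
            total_sq += loss.item() * len(batch)
            total_n += len(batch)
        epoch_loss = total_sq / max(total_n, 1)
        model.history.append(epoch_loss)
        logger.info("epoch %d/%d: training MSE %.5f", epoch + 1, c.epochs, epoch_loss)
    return model


def score_instances(
    model: GDPModel, instances: list[EncodedInstance], batch_size: int = 64
) -> list[PredictionRecord]:
    """GDP scores and binary calls, in input order.

    Scoring a list equals scoring one-by-one; batching only amortizes the
    padded forward pass.
    """
    records: list[PredictionRecord] = []
    for start in range(0, len(instances), batch_size):
        batch = instances[start : start + batch_size]
        scores = model.forward(batch, train=False).data[:, 0]
        for inst, s in zip(batch, scores):
            s = float(s)
            records.append(
                PredictionRecord(
                    doc_id=inst.doc_id,
                    gene_id=inst.pair[0],
                    disease_id=inst.pair[1],
                    gdp_score=s,
                    call=binarize_gdp(s),
                )
            )
    return records
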