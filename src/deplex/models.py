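"""Classifier families for depression-post detection.

Three architectures are provided:

* ``cnn`` — embedding (128-d, optionally word2vec-initialized) → 1-D
  convolution with 128 filters of width 4 → dropout → max-pooling over time
  (one value per filter, output size 128) → two fully connected layers →
  sigmoid probability; binary cross-entropy loss, Adam optimizer.
* ``bilstm`` — same embedding → bidirectional LSTM with 64 units per
  direction → the same two fully connected layers and sigmoid head.
* ``transformer_head`` — a pluggable sentence encoder producing 768-d pooled
  features feeding one fully connected layer; cross-entropy loss, AdamW
  optimizer.  Any pretrained transformer can be adapted by passing a callable
  mapping an (n, max_len) index matrix to (n, 768) features; the shipped
  default is a tiny frozen random-projection encoder for desk-scale runs.

Everything runs on the package's own numpy autograd; all randomness is
seeded through the model config so same-seed runs are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from . import nn
from .features import FeatureMatrix, Vocabulary, encode_posts  # re-exported
from .nn import Tensor

logger = logging.getLogger(__name__)

FAMILIES = ("cnn", "bilstm", "transformer_head")


@dataclass
class ModelConfig:
    family: str = "cnn"
    embed_dim: int = 128
    cnn_filters: int = 128
    cnn_filter_size: int = 4
    pool_size: int = 128
    bilstm_units: int = 64
    fc_layers: int = 2
    fc_hidden: int = 64
    dropout_rate: float = 0.5
    max_len: int = 64
    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")
        for name in ("embed_dim", "cnn_filters", "cnn_filter_size", "bilstm_units", "fc_hidden", "max_len", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.loss not in ("binary_cross_entropy", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def for_family(cls, family: str, **overrides) -> "ModelConfig":
        """Family-consistent defaults: cnn/bilstm use 128-d embeddings, BCE
        and Adam; transformer_head uses 768-d features, CE and AdamW."""
        if family == "transformer_head":
            base = dict(family=family, embed_dim=768, fc_layers=1,
                        loss="cross_entropy", optimizer="adamw", lr=2e-5)
        else:
            base = dict(family=family, embed_dim=128, fc_layers=2,
                        loss="binary_cross_entropy", optimizer="adam", lr=1e-3)
        base.update(overrides)
        return cls(**base)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _embedding_init(rng: np.random.Generator, vocab_size: int, dim: int) -> np.ndarray:
    # pad (0) and unknown (1) rows start at zero: reserved tokens should not
    # inject arbitrary random signal into the encoder (they stay trainable)
    table = rng.uniform(-0.05, 0.05, (vocab_size, dim)).astype(np.float32)
    table[:2] = 0.0
    return table


class _FCHead:
    """Shared fully-connected stack: (in -> hidden -> 1) or (in -> 1)."""

    def __init__(self, rng, in_dim: int, hidden: int, n_layers: int, out_dim: int = 1):
        self.n_layers = n_layers
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        dims = [in_dim] + [hidden] * (n_layers - 1) + [out_dim]
        for a, b in zip(dims[:-1], dims[1:]):
            self.weights.append(Tensor(_glorot(rng, (a, b))))
            self.biases.append(Tensor(np.zeros(b, dtype=np.float32)))
        self.shapes = list(zip(dims[:-1], dims[1:]))

    def __call__(self, x: Tensor) -> Tensor:
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ W + b
            if i < len(self.weights) - 1:
                x = x.relu()
        return x

    def params(self) -> list[Tensor]:
        return self.weights + self.biases


class CNNClassifier:
    """embed → conv(128 filters × width 4) → dropout → max-pool(128) → fc → fc → sigmoid."""

    family = "cnn"

    def __init__(self, config: ModelConfig, vocab_size: int):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        D, F, K = config.embed_dim, config.cnn_filters, config.cnn_filter_size
        self.embedding = Tensor(_embedding_init(rng, vocab_size, D))
        self.conv_weight = Tensor(_glorot(rng, (K * D, F)))
        self.conv_bias = Tensor(np.zeros(F, dtype=np.float32))
        self.head = _FCHead(rng, F, config.fc_hidden, config.fc_layers)

    def params(self) -> list[Tensor]:
        return [self.embedding, self.conv_weight, self.conv_bias] + self.head.params()

    def forward(self, X: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None) -> Tensor:
        e = nn.embedding(self.embedding, X)
        h = nn.conv1d(e, self.conv_weight, self.conv_bias, self.config.cnn_filter_size).relu()
        h = nn.dropout(h, self.config.dropout_rate, rng or np.random.default_rng(0), train)
        pooled = nn.max_over_axis(h, axis=1)
        return self.head(pooled)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.forward(np.asarray(X), train=False)
        return (1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))).astype(np.float64)

    def set_embeddings(self, table: np.ndarray) -> None:
        if table.shape != self.embedding.data.shape:
            raise ValueError(f"embedding table shape {table.shape} != {self.embedding.data.shape}")
        self.embedding.data = table.astype(np.float32)

    def describe(self) -> dict:
        c = self.config
        return {
            "layers": ["embedding", "conv1d", "dropout", "max_pool", "fc", "fc", "sigmoid"],
            "embedding_dim": c.embed_dim,
            "conv": {
                "filters": c.cnn_filters,
                "kernel_size": c.cnn_filter_size,
                "in_dim": c.embed_dim,
                "n_weights": int(self.conv_weight.data.size),
                "n_biases": int(self.conv_bias.data.size),
            },
            "pool_size": c.pool_size,
            "fc_shapes": self.head.shapes,
            "output_activation": "sigmoid",
        }


class _LSTMDirection:
    def __init__(self, rng, in_dim: int, hidden: int):
        self.hidden = hidden
        self.Wx = Tensor(_glorot(rng, (in_dim, 4 * hidden)))
        self.Wh = Tensor(_glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b)

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]

    def run(self, emb: Tensor, timesteps: Iterable[int], batch: int) -> Tensor:
        H = self.hidden
        h = Tensor(np.zeros((batch, H), dtype=np.float32))
        c = Tensor(np.zeros((batch, H), dtype=np.float32))
        for t in timesteps:
            x_t = emb[:, t, :]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class BiLSTMClassifier:
    """embed → bidirectional LSTM (64 units per direction) → fc → fc → sigmoid."""

    family = "bilstm"

    def __init__(self, config: ModelConfig, vocab_size: int):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        D, H = config.embed_dim, config.bilstm_units
        self.embedding = Tensor(_embedding_init(rng, vocab_size, D))
        self.forward_cell = _LSTMDirection(rng, D, H)
        self.backward_cell = _LSTMDirection(rng, D, H)
        self.head = _FCHead(rng, 2 * H, config.fc_hidden, config.fc_layers)

    def params(self) -> list[Tensor]:
        return (
            [self.embedding]
            + self.forward_cell.params()
            + self.backward_cell.params()
            + self.head.params()
        )

    def forward(self, X: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None) -> Tensor:
        X = np.asarray(X)
        B, L = X.shape
        e = nn.embedding(self.embedding, X)
        h_fwd = self.forward_cell.run(e, range(L), B)
        h_bwd = self.backward_cell.run(e, range(L - 1, -1, -1), B)
        h = nn.concat([h_fwd, h_bwd], axis=-1)
        h = nn.dropout(h, self.config.dropout_rate, rng or np.random.default_rng(0), train)
        return self.head(h)

    predict_proba = CNNClassifier.predict_proba
    set_embeddings = CNNClassifier.set_embeddings

    def describe(self) -> dict:
        c = self.config
        return {
            "layers": ["embedding", "bilstm", "dropout", "fc", "fc", "sigmoid"],
            "embedding_dim": c.embed_dim,
            "lstm": {"units_per_direction": c.bilstm_units, "bidirectional": True},
            "fc_shapes": self.head.shapes,
            "output_activation": "sigmoid",
        }


class TinyRandomEncoder:
    """Frozen random-projection sentence encoder (desk-scale stand-in for a
    pretrained transformer; synthetic — carries no pretrained knowledge).

    Mean-pools a fixed random embedding of non-pad tokens through a tanh.
    """

    def __init__(self, vocab_size: int, dim: int = 768, seed: int = 0, pad_index: int = 0):
        rng = np.random.default_rng(seed)
        self.table = rng.normal(0, 0.1, (vocab_size, dim)).astype(np.float32)
        self.pad_index = pad_index
        self.dim = dim

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        mask = (X != self.pad_index).astype(np.float32)[..., None]
        summed = (self.table[X] * mask).sum(axis=1)
        denom = np.maximum(mask.sum(axis=1), 1.0)
        return np.tanh(summed / denom)


class TransformerHeadClassifier:
    """Pooled 768-d encoder features → one fully connected layer → softmax."""

    family = "transformer_head"

    def __init__(
        self,
        config: ModelConfig,
        vocab_size: int,
        encoder: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    ):
        self.config = config
        self.vocab_size = vocab_size
        self.encoder = encoder or TinyRandomEncoder(vocab_size, config.embed_dim, config.seed)
        rng = np.random.default_rng(config.seed)
        self.head = _FCHead(rng, config.embed_dim, config.fc_hidden, config.fc_layers, out_dim=2)

    def params(self) -> list[Tensor]:
        return self.head.params()

    def forward(self, X: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None) -> Tensor:
        feats = Tensor(self.encoder(np.asarray(X)))
        return self.head(feats)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.forward(np.asarray(X)).data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return (e[:, 1] / e.sum(axis=1)).astype(np.float64)

    def describe(self) -> dict:
        return {
            "layers": ["encoder(768)", "fc", "softmax"],
            "feature_dim": self.config.embed_dim,
            "fc_shapes": self.head.shapes,
            "output_activation": "softmax",
        }


Classifier = CNNClassifier | BiLSTMClassifier | TransformerHeadClassifier


def build_classifier(config: ModelConfig, vocab_size: int, encoder=None) -> Classifier:
    """Instantiate an untrained classifier with seeded initialization."""
    if config.family == "cnn":
        return CNNClassifier(config, vocab_size)
    if config.family == "bilstm":
        return BiLSTMClassifier(config, vocab_size)
    return TransformerHeadClassifier(config, vocab_size, encoder)


# ---------------------------------------------------------------------------
# word2vec (skip-gram with negative sampling)

def train_word_embeddings(
    corpus: Sequence[Sequence[str]],
    dim: int = 128,
    seed: int = 0,
    window: int = 5,
    min_count: int = 1,
    negative: int = 5,
    epochs: int = 3,
    lr: float = 0.025,
) -> dict[str, np.ndarray]:
    """Skip-gram negative-sampling embeddings trained on a tokenized corpus.

    Returns token -> vector.  Falls back to seeded random-uniform vectors
    (with a log message) when the corpus yields no training pairs.
    """
    counts = Counter(t for sent in corpus for t in sent)
    vocab = [t for t, c in counts.items() if c >= min_count]
    rng = np.random.default_rng(seed)
    if not vocab:
        logger.warning("word2vec: empty corpus; no embeddings trained")
        return {}
    stoi = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    centers, contexts = [], []
    for sent in corpus:
        idx = [stoi[t] for t in sent if t in stoi]
        for i, c in enumerate(idx):
            for j in range(max(0, i - window), min(len(idx), i + window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(idx[j])
    if not centers:
        logger.warning("word2vec: corpus too small for skip-gram pairs; using random-uniform fallback")
        return {t: rng.uniform(-0.5 / dim, 0.5 / dim, dim).astype(np.float32) for t in vocab}

    centers = np.asarray(centers)
    contexts = np.asarray(contexts)
    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise = freq / freq.sum()

    W_in = rng.uniform(-0.5 / dim, 0.5 / dim, (V, dim)).astype(np.float64)
    W_out = np.zeros((V, dim), dtype=np.float64)
    batch = 1024
    for _ in range(epochs):
        order = rng.permutation(len(centers))
        for start in range(0, len(order), batch):
            sel = order[start : start + batch]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(V, size=(len(sel), negative), p=noise)
            vc = W_in[c]                       # (B, D)
            vo = W_out[o]                      # (B, D)
            vn = W_out[neg]                    # (B, neg, D)
            pos_score = np.clip((vc * vo).sum(axis=1), -12, 12)
            neg_score = np.clip((vn @ vc[:, :, None])[..., 0], -12, 12)
            g_pos = (1.0 / (1.0 + np.exp(-pos_score)) - 1.0)[:, None]
            g_neg = (1.0 / (1.0 + np.exp(-neg_score)))[..., None]
            # average accumulated gradients per token so that tiny
            # vocabularies (many repeats per batch) stay stable
            grad_in = np.zeros_like(W_in)
            grad_out = np.zeros_like(W_out)
            cnt_in = np.zeros(V)
            cnt_out = np.zeros(V)
            np.add.at(grad_in, c, g_pos * vo + (g_neg * vn).sum(axis=1))
            np.add.at(cnt_in, c, 1)
            np.add.at(grad_out, o, g_pos * vc)
            np.add.at(cnt_out, o, 1)
            np.add.at(grad_out.reshape(-1, dim), neg.reshape(-1),
                      (g_neg * vc[:, None, :]).reshape(-1, dim))
            np.add.at(cnt_out, neg.reshape(-1), 1)
            W_in -= lr * grad_in / np.maximum(cnt_in, 1)[:, None]
            W_out -= lr * grad_out / np.maximum(cnt_out, 1)[:, None]
    return {t: W_in[i].astype(np.float32) for t, i in stoi.items()}


def embedding_matrix(
    w2v: dict[str, np.ndarray], vocabulary: Vocabulary, dim: int, seed: int = 0
) -> np.ndarray:
    """Align word2vec vectors to vocabulary indices; unseen rows are seeded
    random-uniform and the reserved pad/unknown rows are zero."""
    rng = np.random.default_rng(seed)
    table = _embedding_init(rng, len(vocabulary), dim)
    for i in range(len(vocabulary)):
        vec = w2v.get(vocabulary.token(i))
        if vec is not None:
            table[i] = vec
    return table


# ---------------------------------------------------------------------------
# training / prediction

@dataclass
class TrainedClassifier:
    classifier: Classifier
    config: ModelConfig
    vocabulary: Optional[Vocabulary] = None
    history: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(X)


def _loss_fn(config: ModelConfig, logits: Tensor, y: np.ndarray) -> Tensor:
    if config.loss == "binary_cross_entropy":
        return nn.bce_with_logits(logits, y)
    return nn.softmax_cross_entropy(logits, y)


def train_classifier(
    clf: Classifier,
    train: FeatureMatrix,
    val: Optional[FeatureMatrix],
    config: Optional[ModelConfig] = None,
    vocabulary: Optional[Vocabulary] = None,
) -> TrainedClassifier:
    """Minibatch training with the config's loss/optimizer; seeded shuffling
    and dropout make same-seed runs reproducible."""
    config = config or clf.config
    if len(train) == 0:
        raise ValueError("training split is empty")
    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels contain a single class; nothing to separate")
    opt_cls = nn.Adam if config.optimizer == "adam" else nn.AdamW
    opt = opt_cls(clf.params(), lr=config.lr)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    n = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            logits = clf.forward(train.X[sel], train=True, rng=rng)
            loss = _loss_fn(config, logits, train.y[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sel)
            seen += len(sel)
        history["train_loss"].append(total / seen)
        if val is not None and len(val):
            vlogits = clf.forward(val.X, train=False)
            history["val_loss"].append(float(_loss_fn(config, vlogits, val.y).data))
    return TrainedClassifier(clf, config, vocabulary, history)


def predict(
    trained: TrainedClassifier | Classifier,
    X: np.ndarray,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities in [0, 1] and hard labels (probability >= threshold)."""
    clf = trained.classifier if isinstance(trained, TrainedClassifier) else trained
    config = trained.config if isinstance(trained, TrainedClassifier) else clf.config
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != config.max_len:
        raise ValueError(f"input width {X.shape} does not match training max_len {config.max_len}")
    probs = clf.predict_proba(X)
    thr = config.threshold if threshold is None else threshold
    return probs, (probs >= thr).astype(np.int64)


# ---------------------------------------------------------------------------
# checkpoints: one .npz archive holding arrays + a JSON header

def save_model(trained: TrainedClassifier, path: str | Path) -> None:
    clf = trained.classifier
    header = {
        "config": asdict(trained.config),
        "vocab": None,
        "history": trained.history,
        "vocab_size": clf.vocab_size,
    }
    if trained.vocabulary is not None:
        header["vocab"] = {
            "tokens": [trained.vocabulary.token(i) for i in range(len(trained.vocabulary))],
            "boundaries": trained.vocabulary.boundaries,
        }
    arrays = {f"p{i}": p.data for i, p in enumerate(clf.params())}
    with open(path, "wb") as fh:
        np.savez(fh, header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as arc:
        header = json.loads(str(arc["header"]))
        config = ModelConfig(**header["config"])
        clf = build_classifier(config, header["vocab_size"])
        for i, p in enumerate(clf.params()):
            p.data = arc[f"p{i}"].astype(np.float32)
    vocab = None
    if header["vocab"] is not None:
        tokens = header["vocab"]["tokens"]
        boundaries = header["vocab"]["boundaries"]
        n_special = 4 if boundaries else 2
        vocab = Vocabulary(tokens[n_special:], boundaries=boundaries)
    return TrainedClassifier(clf, config, vocab, header["history"])
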