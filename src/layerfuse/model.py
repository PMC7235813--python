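"""End-to-end character tagger: encoder -> layer fusion -> softmax head.

The classification head maps each token's fused context embedding E to a
distribution over the 13 BIO labels, ``Y = Softmax(w_O E + b_O)``; the
loss is mean per-token negative log-probability of the gold tag (no CRF
— tags are predicted independently, and structured decoding belongs to
the baseline systems, not this model).  Padding positions are masked
out of both loss and metrics.

Training uses AdamW (Adam with decoupled weight decay on matrix-shaped
parameters), shuffled mini-batches padded to the longest sentence in
the batch, and model selection by validation micro-F1: the checkpoint
with the best validation score is returned.  Everything is driven by a
single integer seed and is bitwise reproducible on a fixed platform.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .aggregate import AGGREGATE_METHODS, AggregatorParams, fuse
from .corpus import AnnotatedSentence, read_column_file
from .encoder import (
    CharVocabulary,
    EncoderConfig,
    TransformerEncoder,
)
from .metrics import MetricReport, evaluate
from .tagging import EntitySpan, O_TAG, tag_vocabulary

__all__ = [
    "TrainConfig",
    "tiny_train_config",
    "OutputHead",
    "MultiLevelTagger",
    "TrainingError",
    "predict_tag_distributions",
    "train",
    "evaluate_model",
    "predict_file",
    "save_checkpoint",
    "load_checkpoint",
]

N_TAGS = 13
_TAGS = tag_vocabulary()


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The mirrored defaults are 10 epochs, batch size 32 and AdamW at
    learning rate 1e-5 — the regime for fine-tuning a large pretrained
    encoder.  The tiny randomly initialized encoder needs a larger step
    size; see :func:`tiny_train_config`.
    """

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-5
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    selection_metric: str = "micro_f1"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def tiny_train_config(seed: int = 0, epochs: int = 10) -> TrainConfig:
    """Desk-scale training profile: same epochs/batch geometry, larger
    learning rate suited to a small from-scratch encoder."""
    return TrainConfig(epochs=epochs, batch_size=32, learning_rate=2e-3,
                       seed=seed)


@dataclass
class OutputHead:
    """Softmax classification head over the 13 tags."""

    w_o: Tensor
    b_o: Tensor

    @classmethod
    def initialize(cls, d: int, seed: int = 0) -> "OutputHead":
        rng = np.random.default_rng(seed)
        return cls(w_o=ad.parameter(rng.normal(0.0, 0.02, (d, N_TAGS))),
                   b_o=ad.parameter(np.zeros(N_TAGS)))

    @property
    def d(self) -> int:
        return self.w_o.data.shape[0]


def predict_tag_distributions(E: np.ndarray, head: OutputHead) -> np.ndarray:
    """Per-token tag distributions Softmax(w_O E + b_O); shape (n, 13).

    Rows are nonnegative and sum to 1; the row argmax defines the
    predicted tag.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[1] != head.d:
        raise ValueError(
            f"context embedding width {E.shape} does not match head "
            f"width {head.d}"
        )
    if not np.all(np.isfinite(E)):
        raise ValueError("non-finite context embedding")
    return ad.softmax(Tensor(E @ head.w_o.data + head.b_o.data), axis=-1).data


def truncate_sentence(sent: AnnotatedSentence, max_len: int) -> AnnotatedSentence:
    """Clip a sentence to ``max_len`` characters, discarding (not
    clipping) any gold span that crosses the boundary."""
    if len(sent.tokens) <= max_len:
        return sent
    kept = tuple(s for s in sent.entities if s.end <= max_len)
    return AnnotatedSentence(sent.tokens[:max_len], kept)


class _AdamW:
    """Adam with decoupled weight decay on matrix-shaped parameters."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, Tensor]) -> None:
        c = self.cfg
        self.t += 1
        for name, p in params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self.m.setdefault(name, np.zeros_like(p.data))
            v = self.v.setdefault(name, np.zeros_like(p.data))
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1 ** self.t)
            vhat = v / (1 - c.beta2 ** self.t)
            if p.data.ndim >= 2:  # no decay on biases / layer-norm params
                p.data -= c.learning_rate * c.weight_decay * p.data
            p.data -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)

    @staticmethod
    def zero_grad(params: Dict[str, Tensor]) -> None:
        for p in params.values():
            p.grad = None


class MultiLevelTagger:
    """Trained (or trainable) tagger bundling all components."""

    def __init__(self, encoder: TransformerEncoder, aggregator: AggregatorParams,
                 head: OutputHead, vocab: CharVocabulary,
                 method: str = "multihead"):
        if method not in AGGREGATE_METHODS:
            raise ValueError(
                f"unknown aggregation method {method!r}; "
                f"expected one of {AGGREGATE_METHODS}"
            )
        self.encoder = encoder
        self.aggregator = aggregator
        self.head = head
        self.vocab = vocab
        self.method = method

    # -- parameters ------------------------------------------------------
    def parameters(self) -> Dict[str, Tensor]:
        p = dict(self.encoder.params)
        for k, t in self.aggregator.tensors().items():
            p["agg." + k] = t
        p["head.w_o"] = self.head.w_o
        p["head.b_o"] = self.head.b_o
        return p

    def parameter_arrays(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_parameter_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(arrays) != set(params):
            raise ValueError("parameter name mismatch on restore")
        for k, t in params.items():
            t.data = np.array(arrays[k], dtype=np.float64)

    # -- forward ---------------------------------------------------------
    def forward_batch(self, ids: np.ndarray, pad_mask: np.ndarray,
                      train: bool = False,
                      rng: Optional[np.random.Generator] = None) -> Tensor:
        stack = self.encoder.forward_ids(ids, pad_mask, train=train, rng=rng)
        E = fuse(self.method, stack, self.aggregator)
        if train and rng is not None:
            E = ad.dropout(E, self.encoder.config.dropout_rate, rng)
        return E @ self.head.w_o + self.head.b_o

    def predict_tags(self, sentences: Sequence[AnnotatedSentence],
                     batch_size: int = 64) -> List[List[str]]:
        """Predicted BIO tags, one sequence per sentence, original
        lengths preserved (positions beyond the encoder's maximum
        sentence length are emitted as O)."""
        max_len = self.encoder.config.max_sentence_length
        out: List[List[str]] = []
        for at in range(0, len(sentences), batch_size):
            chunk = sentences[at : at + batch_size]
            idlists = [self.vocab.encode(list(s.tokens)[:max_len]) for s in chunk]
            ids, mask = _pad_batch(idlists)
            logits = self.forward_batch(ids, mask, train=False)
            pred = np.argmax(logits.data, axis=-1)
            for row, s, n in zip(pred, chunk, (len(x) for x in idlists)):
                tags = [_TAGS[int(j)] for j in row[:n]]
                tags.extend([O_TAG] * (len(s.tokens) - n))
                out.append(tags)
        return out


def _pad_batch(idlists: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    n = max(len(x) for x in idlists)
    ids = np.zeros((len(idlists), n), dtype=np.int64)
    mask = np.zeros((len(idlists), n), dtype=np.float64)
    for i, x in enumerate(idlists):
        ids[i, : len(x)] = x
        mask[i, : len(x)] = 1.0
    return ids, mask


def _label_batch(sentences: Sequence[AnnotatedSentence], n: int) -> np.ndarray:
    tag_index = {t: i for i, t in enumerate(_TAGS)}
    labels = np.zeros((len(sentences), n), dtype=np.int64)
    for i, s in enumerate(sentences):
        for j, t in enumerate(s.tags()):
            labels[i, j] = tag_index[t]
    return labels


def _masked_ce(logits: Tensor, labels: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean negative log-probability of the gold tag over real tokens."""
    logp = ad.log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.data.shape)
    b, n = labels.shape
    onehot[np.arange(b)[:, None], np.arange(n)[None, :], labels] = 1.0
    onehot *= mask[..., None]
    return (logp * Tensor(onehot)).sum() * (-1.0 / mask.sum())


def _mean_eval_loss(model: MultiLevelTagger, batches) -> float:
    total, weight = 0.0, 0.0
    for ids, mask, labels, _ in batches:
        loss = model.forward_batch(ids, mask, train=False)
        total += _masked_ce(loss, labels, mask).data.item() * mask.sum()
        weight += mask.sum()
    return total / weight


def _make_batches(sentences: Sequence[AnnotatedSentence],
                  vocab: CharVocabulary, max_len: int, batch_size: int,
                  order: Optional[np.ndarray] = None):
    if order is None:
        order = np.arange(len(sentences))
    batches = []
    for at in range(0, len(order), batch_size):
        chunk = [truncate_sentence(sentences[i], max_len) for i in order[at : at + batch_size]]
        idlists = [vocab.encode(list(s.tokens)) for s in chunk]
        ids, mask = _pad_batch(idlists)
        labels = _label_batch(chunk, ids.shape[1])
        batches.append((ids, mask, labels, at // batch_size))
    return batches


def train(train_set: Sequence[AnnotatedSentence],
          validation_set: Sequence[AnnotatedSentence],
          encoder_config: EncoderConfig,
          aggregator: Optional[AggregatorParams] = None,
          train_config: Optional[TrainConfig] = None,
          method: str = "multihead",
          layer_subset="all",
          n_fusion_heads: Optional[int] = None,
          ) -> Tuple[MultiLevelTagger, dict]:
    """Train a tagger and return (model, history).

    The character vocabulary is built from the training set (unseen
    characters map to UNK).  History records the pre-training loss (for
    a 13-way softmax at random initialization it sits near log 13) and,
    per epoch, the mean training loss and validation micro-F1.  The
    returned model carries the parameters of the epoch with the best
    validation micro-F1.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if len(validation_set) == 0:
        raise ValueError("empty validation set")
    train_config = train_config or TrainConfig()

    vocab = CharVocabulary.from_sentences(train_set)
    cfg = replace(encoder_config, vocabulary_size=len(vocab))
    encoder = TransformerEncoder(cfg)
    if aggregator is None:
        heads = n_fusion_heads or cfg.n_encoder_heads
        aggregator = AggregatorParams.initialize(
            d=cfg.hidden_size, n_layers=cfg.n_layers,
            layer_subset=layer_subset, n_fusion_heads=heads,
            seed=cfg.seed + 1,
        )
    head = OutputHead.initialize(cfg.hidden_size, seed=cfg.seed + 2)
    model = MultiLevelTagger(encoder, aggregator, head, vocab, method=method)

    params = model.parameters()
    opt = _AdamW(train_config)
    rng = np.random.default_rng(train_config.seed)
    max_len = cfg.max_sentence_length

    eval_batches = _make_batches(train_set[: 4 * train_config.batch_size],
                                 vocab, max_len, train_config.batch_size)
    initial_loss = _mean_eval_loss(model, eval_batches)

    history: dict = {"initial_loss": initial_loss, "epochs": []}
    best_f1 = -1.0
    best_arrays = model.parameter_arrays()
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for ids, mask, labels, bi in _make_batches(
                train_set, vocab, max_len, train_config.batch_size, order):
            opt.zero_grad(params)
            logits = model.forward_batch(ids, mask, train=True, rng=rng)
            loss = _masked_ce(logits, labels, mask)
            val = loss.data.item()
            if not np.isfinite(val):
                raise TrainingError(f"non-finite loss in epoch {epoch}, batch {bi}")
            loss.backward()
            opt.step(params)
            losses.append(val)
        report = evaluate(list(validation_set), model.predict_tags(validation_set))
        f1 = report.micro.f1
        history["epochs"].append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "valid_micro_f1": f1,
        })
        if f1 > best_f1:
            best_f1 = f1
            best_arrays = model.parameter_arrays()
    model.load_parameter_arrays(best_arrays)
    history["best_valid_micro_f1"] = best_f1
    return model, history


def evaluate_model(model: MultiLevelTagger,
                   sentences: Sequence[AnnotatedSentence]) -> MetricReport:
    """Strict entity-level scores of the model on annotated sentences."""
    return evaluate(list(sentences), model.predict_tags(sentences))


def predict_file(model: MultiLevelTagger, column_file_in, column_file_out) -> None:
    """Tag a column file: same tokens, predicted tags, same sentence count."""
    sentences = read_column_file(column_file_in)
    predictions = model.predict_tags(sentences)
    with open(column_file_out, "w", encoding="utf-8") as fh:
        for i, (sent, tags) in enumerate(zip(sentences, predictions)):
            if i:
                fh.write("\n")
            for ch, tag in zip(sent.tokens, tags):
                fh.write(f"{ch}\t{tag}\n")


# -- checkpointing -------------------------------------------------------

def save_checkpoint(model: MultiLevelTagger, path: str) -> None:
    """Write parameters (npz) and configuration (json) to a directory."""
    os.makedirs(path, exist_ok=True)
    np.savez(os.path.join(path, "params.npz"), **model.parameter_arrays())
    meta = {
        "encoder_config": dataclasses.asdict(model.encoder.config),
        "aggregator": {
            "d": model.aggregator.d,
            "n_layers": model.aggregator.n_layers,
            "layer_subset": list(model.aggregator.layer_subset),
            "n_fusion_heads": model.aggregator.n_fusion_heads,
        },
        "method": model.method,
        "vocab": model.vocab.to_dict(),
    }
    with open(os.path.join(path, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, ensure_ascii=False, indent=1)


def load_checkpoint(path: str) -> MultiLevelTagger:
    """Rebuild a tagger from :func:`save_checkpoint` output."""
    with open(os.path.join(path, "meta.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    cfg = EncoderConfig(**meta["encoder_config"])
    agg_meta = meta["aggregator"]
    aggregator = AggregatorParams.initialize(
        d=agg_meta["d"], n_layers=agg_meta["n_layers"],
        layer_subset=tuple(agg_meta["layer_subset"]),
        n_fusion_heads=agg_meta["n_fusion_heads"],
    )
    encoder = TransformerEncoder(cfg)
    head = OutputHead.initialize(cfg.hidden_size)
    vocab = CharVocabulary.from_dict(meta["vocab"])
    model = MultiLevelTagger(encoder, aggregator, head, vocab,
                             method=meta["method"])
    with np.load(os.path.join(path, "params.npz")) as npz:
        model.load_parameter_arrays({k: npz[k] for k in npz.files})
    return model
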