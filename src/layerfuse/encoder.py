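"""Tiny transformer encoder exposing every layer's hidden states.

The multi-level fusion downstream needs the full stack of per-layer
hidden states h_1..h_L, not just the final layer, so :meth:`encode`
returns a :class:`LayerStack` with one ``(n, d)`` array per layer.

The input embedding is the elementwise sum of a token embedding, a
segment embedding and a (learned) position embedding.  The task is
single-sentence tagging, so one segment id is used everywhere, and no
special boundary tokens are inserted: every position corresponds to a
taggable character.  Each transform block is a standard post-layer-norm
encoder layer (self-attention, then a GELU feed-forward of width 4d,
each wrapped in residual + layer norm).

The encoder trains from random initialization on the task loss; it is a
seam: :func:`load_pretrained_adapter` accepts externally supplied
parameters with the same shapes, so pretrained weights can be dropped in
without touching the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "EncoderConfig",
    "tiny_encoder_config",
    "CharVocabulary",
    "LayerStack",
    "TransformerEncoder",
    "load_pretrained_adapter",
    "AdapterError",
    "SentenceLengthError",
]

PAD_INDEX = 0
UNK_INDEX = 1


class AdapterError(ValueError):
    """External parameters do not match the encoder contract."""


class SentenceLengthError(ValueError):
    """Sentence exceeds max_sentence_length with truncation disabled."""


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters.

    Defaults mirror the BERT-base geometry (12 layers, hidden size 768,
    12 self-attention heads, maximum sentence length 64, dropout 0.3);
    desk-scale work uses :func:`tiny_encoder_config`.
    """

    n_layers: int = 12
    hidden_size: int = 768
    n_encoder_heads: int = 12
    vocabulary_size: int = 128
    max_sentence_length: int = 64
    dropout_rate: float = 0.3
    ffn_multiplier: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_size < 1 or self.vocabulary_size < 2:
            raise ValueError("n_layers, hidden_size >= 1 and vocabulary_size >= 2 required")
        if self.hidden_size % self.n_encoder_heads != 0:
            raise ValueError(
                f"hidden_size {self.hidden_size} not divisible by "
                f"n_encoder_heads {self.n_encoder_heads}"
            )
        if self.max_sentence_length < 1:
            raise ValueError("max_sentence_length must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


def tiny_encoder_config(vocabulary_size: int = 128, seed: int = 0,
                        dropout_rate: float = 0.1) -> EncoderConfig:
    """Desk-scale geometry: 4 layers, hidden size 64, 4 heads."""
    return EncoderConfig(
        n_layers=4, hidden_size=64, n_encoder_heads=4,
        vocabulary_size=vocabulary_size, max_sentence_length=64,
        dropout_rate=dropout_rate, seed=seed,
    )


class CharVocabulary:
    """Character-to-index map with reserved PAD (0) and UNK (1) slots."""

    def __init__(self, chars: Sequence[str]):
        self.chars: List[str] = list(dict.fromkeys(chars))
        self.index: Dict[str, int] = {c: i + 2 for i, c in enumerate(self.chars)}

    @classmethod
    def from_sentences(cls, sentences) -> "CharVocabulary":
        seen: Dict[str, None] = {}
        for s in sentences:
            for ch in s.tokens:
                seen.setdefault(ch, None)
        return cls(sorted(seen))

    def __len__(self) -> int:
        return len(self.chars) + 2

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.index.get(c, UNK_INDEX) for c in tokens], dtype=np.int64)

    def to_dict(self) -> dict:
        return {"chars": self.chars}

    @classmethod
    def from_dict(cls, d: dict) -> "CharVocabulary":
        return cls(d["chars"])


class LayerStack:
    """Hidden states h_1..h_L for one sentence: L arrays of shape (n, d)."""

    def __init__(self, layers: Sequence[np.ndarray]):
        layers = [np.asarray(h, dtype=np.float64) for h in layers]
        if not layers:
            raise ValueError("LayerStack needs at least one layer")
        shape = layers[0].shape
        for h in layers:
            if h.ndim != 2 or h.shape != shape:
                raise ValueError("all layers must share one (n, d) shape")
            if not np.all(np.isfinite(h)):
                raise ValueError("non-finite values in hidden states")
        self.layers: List[np.ndarray] = layers

    @property
    def L(self) -> int:
        return len(self.layers)

    @property
    def n(self) -> int:
        return self.layers[0].shape[0]

    @property
    def d(self) -> int:
        return self.layers[0].shape[1]

    def layer(self, l: int) -> np.ndarray:
        """1-based layer access; ``layer(L)`` is the final hidden state."""
        if not (1 <= l <= self.L):
            raise IndexError(f"layer index {l} outside 1..{self.L}")
        return self.layers[l - 1]

    @property
    def last(self) -> np.ndarray:
        return self.layers[-1]


def _init_params(cfg: EncoderConfig) -> Dict[str, Tensor]:
    rng = np.random.default_rng(cfg.seed)
    d, f = cfg.hidden_size, cfg.ffn_multiplier * cfg.hidden_size

    def normal(*shape):
        return ad.parameter(rng.normal(0.0, 0.02, size=shape))

    p: Dict[str, Tensor] = {
        "embed.token": normal(cfg.vocabulary_size, d),
        "embed.segment": normal(2, d),
        "embed.position": normal(cfg.max_sentence_length, d),
    }
    for l in range(1, cfg.n_layers + 1):
        pre = f"layer{l}."
        for name in ("attn.wq", "attn.wk", "attn.wv", "attn.wo"):
            p[pre + name] = normal(d, d)
        for name in ("attn.bq", "attn.bk", "attn.bv", "attn.bo"):
            p[pre + name] = ad.parameter(np.zeros(d))
        p[pre + "ffn.w1"] = normal(d, f)
        p[pre + "ffn.b1"] = ad.parameter(np.zeros(f))
        p[pre + "ffn.w2"] = normal(f, d)
        p[pre + "ffn.b2"] = ad.parameter(np.zeros(d))
        for ln in ("ln1", "ln2"):
            p[pre + ln + ".g"] = ad.parameter(np.ones(d))
            p[pre + ln + ".b"] = ad.parameter(np.zeros(d))
    return p


class TransformerEncoder:
    """Character-level transformer encoder returning all layer states."""

    def __init__(self, config: EncoderConfig,
                 params: Optional[Dict[str, Tensor]] = None):
        self.config = config
        self.params = params if params is not None else _init_params(config)

    # -- parameter plumbing ---------------------------------------------
    def parameter_arrays(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def n_parameters(self) -> int:
        return sum(v.data.size for v in self.params.values())

    # -- forward --------------------------------------------------------
    def _embed_ids(self, ids: np.ndarray) -> Tensor:
        n = ids.shape[-1]
        tok = ad.take_rows(self.params["embed.token"], ids)
        seg = ad.take_rows(self.params["embed.segment"],
                           np.zeros_like(ids))
        pos = ad.take_rows(self.params["embed.position"],
                           np.broadcast_to(np.arange(n), ids.shape))
        return tok + seg + pos

    def _block(self, l: int, h: Tensor, neg_mask: Optional[np.ndarray],
               train: bool, rng: Optional[np.random.Generator]) -> Tensor:
        cfg = self.config
        p = self.params
        pre = f"layer{l}."
        d = cfg.hidden_size
        nh = cfg.n_encoder_heads
        dh = d // nh
        n = h.shape[-2]
        batch_dims = h.shape[:-2]

        def split_heads(x: Tensor) -> Tensor:
            x = x.reshape(*batch_dims, n, nh, dh)
            axes = tuple(range(len(batch_dims))) + (
                len(batch_dims) + 1, len(batch_dims), len(batch_dims) + 2)
            return x.transpose(*axes)  # (..., nh, n, dh)

        q = split_heads(h @ p[pre + "attn.wq"] + p[pre + "attn.bq"])
        k = split_heads(h @ p[pre + "attn.wk"] + p[pre + "attn.bk"])
        v = split_heads(h @ p[pre + "attn.wv"] + p[pre + "attn.bv"])
        kt_axes = tuple(range(len(batch_dims) + 1)) + (
            len(batch_dims) + 2, len(batch_dims) + 1)
        logits = (q @ k.transpose(*kt_axes)) * (1.0 / math.sqrt(dh))
        if neg_mask is not None:
            # neg_mask: (..., 1, 1, n) with -inf-like penalty on padding keys
            logits = logits + Tensor(neg_mask)
        attn = ad.softmax(logits, axis=-1)
        ctx = attn @ v  # (..., nh, n, dh)
        inv_axes = tuple(range(len(batch_dims))) + (
            len(batch_dims) + 1, len(batch_dims), len(batch_dims) + 2)
        ctx = ctx.transpose(*inv_axes).reshape(*batch_dims, n, d)
        ctx = ctx @ p[pre + "attn.wo"] + p[pre + "attn.bo"]
        if train and rng is not None:
            ctx = ad.dropout(ctx, cfg.dropout_rate, rng)
        h = ad.layer_norm(h + ctx, p[pre + "ln1.g"], p[pre + "ln1.b"])
        ff = ad.gelu(h @ p[pre + "ffn.w1"] + p[pre + "ffn.b1"])
        ff = ff @ p[pre + "ffn.w2"] + p[pre + "ffn.b2"]
        if train and rng is not None:
            ff = ad.dropout(ff, cfg.dropout_rate, rng)
        return ad.layer_norm(h + ff, p[pre + "ln2.g"], p[pre + "ln2.b"])

    def forward_ids(self, ids: np.ndarray, pad_mask: Optional[np.ndarray] = None,
                    train: bool = False,
                    rng: Optional[np.random.Generator] = None) -> List[Tensor]:
        """Run the encoder on an id array of shape (..., n).

        Returns the list [h_1, ..., h_L] of per-layer hidden states as
        autodiff tensors.  ``pad_mask`` is 1 for real tokens, 0 for
        padding; padded key positions are excluded from self-attention.
        """
        if ids.shape[-1] < 1:
            raise ValueError("empty sentence")
        if ids.shape[-1] > self.config.max_sentence_length:
            raise SentenceLengthError(
                f"sentence length {ids.shape[-1]} exceeds "
                f"max_sentence_length {self.config.max_sentence_length}"
            )
        neg_mask = None
        if pad_mask is not None:
            neg = (1.0 - pad_mask.astype(np.float64)) * -1e9
            neg_mask = neg[..., None, None, :]
        h = self._embed_ids(ids)
        stack: List[Tensor] = []
        for l in range(1, self.config.n_layers + 1):
            h = self._block(l, h, neg_mask, train, rng)
            stack.append(h)
        return stack

    # -- public single-sentence API -------------------------------------
    def _ids_for(self, tokens, vocab: Optional[CharVocabulary]) -> np.ndarray:
        if isinstance(tokens, np.ndarray):
            return tokens.astype(np.int64)
        if vocab is None:
            raise ValueError("a CharVocabulary is required for string tokens")
        return vocab.encode(list(tokens))

    def embed(self, tokens, vocab: Optional[CharVocabulary] = None) -> np.ndarray:
        """Input embedding: elementwise sum of token, segment and position
        lookups for one sentence; shape (n, d)."""
        ids = self._ids_for(tokens, vocab)
        if ids.size == 0:
            raise ValueError("empty sentence")
        if ids.shape[-1] > self.config.max_sentence_length:
            raise SentenceLengthError(
                f"sentence length {ids.shape[-1]} exceeds "
                f"max_sentence_length {self.config.max_sentence_length}"
            )
        return self._embed_ids(ids).data

    def encode(self, tokens, vocab: Optional[CharVocabulary] = None) -> LayerStack:
        """Hidden states of every layer for one sentence (evaluation
        mode: deterministic, no dropout)."""
        ids = self._ids_for(tokens, vocab)
        return LayerStack([h.data for h in self.forward_ids(ids)])


def load_pretrained_adapter(source) -> TransformerEncoder:
    """Wrap externally supplied encoder parameters in the same contract.

    ``source`` is either another :class:`TransformerEncoder` (identity
    adapter) or a mapping with keys ``"config"`` (an
    :class:`EncoderConfig` or its field dict) and ``"params"`` (name ->
    array).  Shapes are validated against a freshly initialized encoder
    of the same geometry; any mismatch raises :class:`AdapterError`.
    """
    if isinstance(source, TransformerEncoder):
        cfg = source.config
        arrays = source.parameter_arrays()
    else:
        try:
            cfg = source["config"]
            arrays = dict(source["params"])
        except (TypeError, KeyError) as e:
            raise AdapterError(f"adapter source missing config/params: {e}")
        if not isinstance(cfg, EncoderConfig):
            cfg = EncoderConfig(**cfg)
    ref = _init_params(cfg)
    if set(arrays) != set(ref):
        missing = set(ref) - set(arrays)
        extra = set(arrays) - set(ref)
        raise AdapterError(
            f"parameter name mismatch: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    params: Dict[str, Tensor] = {}
    for name, t in ref.items():
        arr = np.asarray(arrays[name], dtype=np.float64)
        if arr.shape != t.data.shape:
            raise AdapterError(
                f"shape mismatch for {name}: got {arr.shape}, "
                f"expected {t.data.shape}"
            )
        params[name] = ad.parameter(arr.copy())
    return TransformerEncoder(cfg, params)
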