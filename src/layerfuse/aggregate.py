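"""Fusing per-layer hidden states into one context embedding per token.

The headline strategy is *layer-attention fusion*: for each token
independently, its hidden vectors from the selected encoder layers act
as the key/value items of a multi-head scaled dot-product attention, and
the query is that token's final-layer state,

    Q   = w_Q h_L + b_Q
    K_l = w_K h_l + b_K          (one item per selected layer l)
    V_l = w_V h_l + b_V
    head_i = softmax(Q_i K_i^T / sqrt(d_head)) V_i
    E   = Concat(head_1, ..., head_H) w_h + b_h

so each head learns a mixture over depths.  Attention is over *layers*,
never over sequence positions; cross-token mixing happens only inside
the encoder.  The scaling denominator is the per-head key dimension
d_head = d / H.

Three comparison strategies share the interface: feature-axis
concatenation of the selected layers followed by a linear projection
back to width d, the unweighted per-layer mean (sum-average), and the
plain last layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .encoder import LayerStack

__all__ = [
    "AggregatorParams",
    "AggregatorConfigError",
    "AGGREGATE_METHODS",
    "resolve_layer_subset",
    "aggregate_multihead",
    "aggregate_concat",
    "aggregate_sum_average",
    "aggregate_last_layer",
    "multihead_attention_weights",
]

AGGREGATE_METHODS = ("multihead", "concat", "sum_average", "last_layer")

SubsetSpec = Union[str, Sequence[int]]


class AggregatorConfigError(ValueError):
    """Aggregator parameters violate their contract."""


def resolve_layer_subset(spec: SubsetSpec, n_layers: int) -> Tuple[int, ...]:
    """Turn ``"all"``/``"last2"``/``"last4"``/``"last6"`` or an explicit
    1-based list into a sorted layer tuple; the final layer must belong."""
    if isinstance(spec, str):
        if spec == "all":
            subset = range(1, n_layers + 1)
        elif spec.startswith("last"):
            k = int(spec[4:])
            if k > n_layers:
                raise AggregatorConfigError(
                    f"subset {spec!r} needs {k} layers but the encoder has {n_layers}"
                )
            subset = range(n_layers - k + 1, n_layers + 1)
        else:
            raise AggregatorConfigError(f"unknown layer subset spec {spec!r}")
    else:
        subset = spec
    out = tuple(sorted(set(int(l) for l in subset)))
    if not out:
        raise AggregatorConfigError("layer subset must be non-empty")
    if out[0] < 1 or out[-1] > n_layers:
        raise AggregatorConfigError(
            f"layer subset {out} outside 1..{n_layers}"
        )
    if n_layers not in out:
        raise AggregatorConfigError(
            f"layer subset {out} must contain the final layer {n_layers}"
        )
    return out


@dataclass
class AggregatorParams:
    """Projection and mixing weights of the fusion step.

    ``w_q``..``b_h`` drive the multi-head strategy; ``w_c``/``b_c`` is
    the concat strategy's (|subset|*d, d) projection.  All arrays are
    autodiff parameters so the fusion trains jointly with the encoder.
    """

    d: int
    n_layers: int
    layer_subset: Tuple[int, ...]
    n_fusion_heads: int
    w_q: Tensor
    b_q: Tensor
    w_k: Tensor
    b_k: Tensor
    w_v: Tensor
    b_v: Tensor
    w_h: Tensor
    b_h: Tensor
    w_c: Tensor
    b_c: Tensor

    def __post_init__(self):
        if self.d % self.n_fusion_heads != 0:
            raise AggregatorConfigError(
                f"hidden size {self.d} not divisible by "
                f"n_fusion_heads {self.n_fusion_heads}"
            )
        self.layer_subset = resolve_layer_subset(self.layer_subset, self.n_layers)
        s = len(self.layer_subset)
        expect = {
            "w_q": (self.d, self.d), "b_q": (self.d,),
            "w_k": (self.d, self.d), "b_k": (self.d,),
            "w_v": (self.d, self.d), "b_v": (self.d,),
            "w_h": (self.d, self.d), "b_h": (self.d,),
            "w_c": (s * self.d, self.d), "b_c": (self.d,),
        }
        for name, shape in expect.items():
            got = getattr(self, name).data.shape
            if got != shape:
                raise AggregatorConfigError(
                    f"{name} has shape {got}, expected {shape}"
                )

    @property
    def d_head(self) -> int:
        return self.d // self.n_fusion_heads

    @classmethod
    def initialize(cls, d: int, n_layers: int,
                   layer_subset: SubsetSpec = "all",
                   n_fusion_heads: int = 12, seed: int = 0) -> "AggregatorParams":
        """Random-normal projections (std 0.02), zero biases."""
        subset = resolve_layer_subset(layer_subset, n_layers)
        rng = np.random.default_rng(seed)

        def normal(*shape):
            return ad.parameter(rng.normal(0.0, 0.02, size=shape))

        zeros = lambda *shape: ad.parameter(np.zeros(shape))
        return cls(
            d=d, n_layers=n_layers, layer_subset=subset,
            n_fusion_heads=n_fusion_heads,
            w_q=normal(d, d), b_q=zeros(d),
            w_k=normal(d, d), b_k=zeros(d),
            w_v=normal(d, d), b_v=zeros(d),
            w_h=normal(d, d), b_h=zeros(d),
            w_c=normal(len(subset) * d, d), b_c=zeros(d),
        )

    @classmethod
    def identity(cls, d: int, n_layers: int,
                 layer_subset: SubsetSpec = "all",
                 n_fusion_heads: int = 1, zero_query: bool = False,
                 seed: int = 0) -> "AggregatorParams":
        """Identity value/mix projections and zero biases.

        With ``zero_query=True`` the query is the zero vector, forcing
        uniform attention over the subset.  The concat projection is the
        block-averaging map, which reduces to the identity for a
        single-layer subset.
        """
        subset = resolve_layer_subset(layer_subset, n_layers)
        rng = np.random.default_rng(seed)
        s = len(subset)
        eye = np.eye(d)
        w_q = np.zeros((d, d)) if zero_query else rng.normal(0.0, 0.02, (d, d))
        return cls(
            d=d, n_layers=n_layers, layer_subset=subset,
            n_fusion_heads=n_fusion_heads,
            w_q=ad.parameter(w_q), b_q=ad.parameter(np.zeros(d)),
            w_k=ad.parameter(rng.normal(0.0, 0.02, (d, d))),
            b_k=ad.parameter(np.zeros(d)),
            w_v=ad.parameter(eye.copy()), b_v=ad.parameter(np.zeros(d)),
            w_h=ad.parameter(eye.copy()), b_h=ad.parameter(np.zeros(d)),
            w_c=ad.parameter(np.tile(eye / s, (s, 1))),
            b_c=ad.parameter(np.zeros(d)),
        )

    def tensors(self) -> Dict[str, Tensor]:
        return {name: getattr(self, name)
                for name in ("w_q", "b_q", "w_k", "b_k", "w_v", "b_v",
                             "w_h", "b_h", "w_c", "b_c")}


# -- tensor-path internals (shared by inference API and training) --------

def _select(layers: Sequence[Tensor], params_subset: Tuple[int, ...],
            n_layers: int) -> List[Tensor]:
    if len(layers) != n_layers:
        raise AggregatorConfigError(
            f"stack has {len(layers)} layers, aggregator expects {n_layers}"
        )
    return [layers[l - 1] for l in params_subset]


def fuse_multihead(layers: Sequence[Tensor], params: AggregatorParams,
                   return_weights: bool = False):
    """Layer-attention fusion on tensors of shape (..., n, d)."""
    sel = _select(layers, params.layer_subset, params.n_layers)
    h_last = layers[-1]
    nb = len(h_last.shape) - 2
    n, d = h_last.shape[-2], h_last.shape[-1]
    nh, dh, s = params.n_fusion_heads, params.d_head, len(sel)
    batch = h_last.shape[:nb]

    q = h_last @ params.w_q + params.b_q
    q = q.reshape(*batch, n, nh, 1, dh)
    k = ad.stack([h @ params.w_k + params.b_k for h in sel], axis=-2)
    v = ad.stack([h @ params.w_v + params.b_v for h in sel], axis=-2)
    # (..., n, S, d) -> (..., n, H, S, dh)
    perm = tuple(range(nb + 1)) + (nb + 2, nb + 1, nb + 3)
    k = k.reshape(*batch, n, s, nh, dh).transpose(*perm)
    v = v.reshape(*batch, n, s, nh, dh).transpose(*perm)
    swap_last = tuple(range(nb + 2)) + (nb + 3, nb + 2)
    logits = (q @ k.transpose(*swap_last)) * (1.0 / math.sqrt(dh))
    attn = ad.softmax(logits, axis=-1)          # (..., n, H, 1, S)
    ctx = attn @ v                               # (..., n, H, 1, dh)
    ctx = ctx.reshape(*batch, n, d)              # concat heads
    out = ctx @ params.w_h + params.b_h
    if return_weights:
        w = attn.data.reshape(*batch, n, nh, s)
        return out, w
    return out


def fuse_concat(layers: Sequence[Tensor], params: AggregatorParams) -> Tensor:
    sel = _select(layers, params.layer_subset, params.n_layers)
    wide = ad.concat(sel, axis=-1)               # (..., n, S*d)
    return wide @ params.w_c + params.b_c


def fuse_sum_average(layers: Sequence[Tensor],
                     subset: Tuple[int, ...], n_layers: int) -> Tensor:
    sel = _select(layers, subset, n_layers)
    out = sel[0]
    for h in sel[1:]:
        out = out + h
    return out * (1.0 / len(sel))


def fuse(method: str, layers: Sequence[Tensor],
         params: AggregatorParams) -> Tensor:
    if method == "multihead":
        return fuse_multihead(layers, params)
    if method == "concat":
        return fuse_concat(layers, params)
    if method == "sum_average":
        return fuse_sum_average(layers, params.layer_subset, params.n_layers)
    if method == "last_layer":
        return layers[-1]
    raise AggregatorConfigError(
        f"unknown aggregation method {method!r}; expected one of {AGGREGATE_METHODS}"
    )


# -- public numpy API over a LayerStack ----------------------------------

def _as_tensors(stack: LayerStack) -> List[Tensor]:
    return [Tensor(h) for h in stack.layers]


def aggregate_multihead(stack: LayerStack, params: AggregatorParams) -> np.ndarray:
    """Context embedding (n, d) from layer-attention fusion."""
    return fuse_multihead(_as_tensors(stack), params).data


def multihead_attention_weights(stack: LayerStack,
                                params: AggregatorParams) -> np.ndarray:
    """Per-token, per-head attention over the layer subset; shape
    (n, n_fusion_heads, |subset|).  Rows are softmax distributions."""
    _, w = fuse_multihead(_as_tensors(stack), params, return_weights=True)
    return w


def aggregate_concat(stack: LayerStack, params: AggregatorParams) -> np.ndarray:
    """Feature-axis concatenation of the selected layers, projected back
    to width d."""
    return fuse_concat(_as_tensors(stack), params).data


def aggregate_sum_average(stack: LayerStack,
                          layer_subset: SubsetSpec = "all") -> np.ndarray:
    """Unweighted elementwise mean of the selected layers."""
    subset = resolve_layer_subset(layer_subset, stack.L)
    return fuse_sum_average(_as_tensors(stack), subset, stack.L).data


def aggregate_last_layer(stack: LayerStack) -> np.ndarray:
    """The final layer h_L unchanged."""
    return stack.last.copy()
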