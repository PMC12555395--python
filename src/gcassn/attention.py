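"""Self-attention block with Laplacian-style residual enhancement.

The block projects the graph features to a shared query/key space reduced
4-fold in width (Q and K use the *same* parameters), forms the raw score
``Q K^T`` with no additional scaling, row-softmaxes it into a stochastic
attention weight, and aggregates the value projection.  The residual path

    F_attention = LBR(F_in - F_sa) + F_in

feeds the offset between input and attention output through a linear +
batch-norm + ReLU stack and adds the input back.  Because the attention
weight is row-stochastic, ``F_in - F_sa`` with an identity value map acts on
features like the combinatorial graph Laplacian ``D - E`` (it annihilates
point-constant features), which is the interpretation behind the design.

``general`` (unshared Q/K) and multi-head variants are provided for the
design-space comparison harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm, Linear, Module, Sequential, ReLU

__all__ = [
    "AttentionParams", "AttentionState", "MultiHeadParams",
    "self_attention_forward", "laplacian_enhance", "attention_forward",
    "multihead_attention_forward",
]

VARIANTS = ("gcasm", "general", "multihead4", "multihead8")


@dataclass
class AttentionState:
    """Intermediates of one attention pass, exposed for inspection/tests."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    score: np.ndarray      # (..., N, N) raw Q K^T
    weight: np.ndarray     # (..., N, N) row-stochastic
    F_sa: np.ndarray


class AttentionParams(Module):
    """Shared-QK single-head attention parameters plus the LBR stack.

    ``W_qk`` maps C -> C/4 and serves as both the query and the key
    projection (one underlying parameter set); ``W_v`` maps C -> C.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 variant: str = "gcasm"):
        super().__init__()
        if channels % 4 != 0:
            raise ValueError("channel width must be divisible by 4")
        if variant not in ("gcasm", "general"):
            raise ValueError(f"unknown single-head variant {variant!r}")
        self.channels = channels
        self.variant = variant
        self.W_qk = Linear(channels, channels // 4, rng, bias=False)
        # the general variant un-shares the projections
        self.W_k_general = (Linear(channels, channels // 4, rng, bias=False)
                            if variant == "general" else None)
        self.W_v = Linear(channels, channels, rng, bias=False)
        self.lbr = Sequential(Linear(channels, channels, rng),
                              BatchNorm(channels), ReLU())

    @property
    def W_q(self) -> Linear:
        return self.W_qk

    @property
    def W_k(self) -> Linear:
        return self.W_k_general if self.variant == "general" else self.W_qk


def self_attention_forward(F_in, params: AttentionParams):
    """Single-head attention pass; returns ``(F_sa, state)``.

    ``F_sa = softmax(Q K^T) V`` with Q = K = F_in W_qk (shared parameters)
    and V = F_in W_v.  Softmax normalizes each query row over the keys, so
    every row of the weight matrix sums to one.
    """
    is_tensor = isinstance(F_in, Tensor)
    x = F_in if is_tensor else Tensor(np.asarray(F_in, dtype=np.float64))
    if x.shape[-1] != params.channels:
        raise ValueError(f"expected {params.channels} channels, got {x.shape[-1]}")
    Q = params.W_q(x)
    K = params.W_k(x)
    V = params.W_v(x)
    score = Q @ K.swapaxes(-1, -2)          # no 1/sqrt(d) factor
    weight = ad.softmax(score, axis=-1)
    F_sa = weight @ V
    state = AttentionState(Q.data, K.data, V.data, score.data, weight.data,
                           F_sa.data)
    return (F_sa, state) if is_tensor else (F_sa.data, state)


def laplacian_enhance(F_in, F_sa, params: AttentionParams):
    """Residual enhancement ``LBR(F_in - F_sa) + F_in``.

    In eval mode the batch-norm inside LBR uses its stored running
    statistics, making the map deterministic.
    """
    is_tensor = isinstance(F_in, Tensor)
    x = F_in if isinstance(F_in, Tensor) else Tensor(np.asarray(F_in, dtype=np.float64))
    s = F_sa if isinstance(F_sa, Tensor) else Tensor(np.asarray(F_sa, dtype=np.float64))
    if x.shape != s.shape:
        raise ValueError("F_in and F_sa must have identical shapes")
    out = params.lbr(x - s) + x
    return out if is_tensor else out.data


def attention_forward(F_in, params: "AttentionParams | MultiHeadParams"):
    """Full attention block (any variant): attention then enhancement."""
    if isinstance(params, MultiHeadParams):
        F_sa = multihead_attention_forward(F_in, params)
        return laplacian_enhance_mh(F_in, F_sa, params)
    F_sa, _ = self_attention_forward(F_in, params)
    return laplacian_enhance(F_in, F_sa, params)


class MultiHeadParams(Module):
    """Standard multi-head generalization used by the comparison harness."""

    def __init__(self, channels: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if channels % n_heads != 0:
            raise ValueError(f"channels {channels} not divisible by "
                             f"{n_heads} heads")
        self.channels = channels
        self.n_heads = n_heads
        d = channels // n_heads
        self.W_q = [Linear(channels, d, rng, bias=False) for _ in range(n_heads)]
        self.W_k = [Linear(channels, d, rng, bias=False) for _ in range(n_heads)]
        self.W_v = [Linear(channels, d, rng, bias=False) for _ in range(n_heads)]
        self.W_o = Linear(channels, channels, rng, bias=False)
        self.lbr = Sequential(Linear(channels, channels, rng),
                              BatchNorm(channels), ReLU())


def multihead_attention_forward(F_in, params: MultiHeadParams):
    """Per-head attention, concatenation, and output projection."""
    is_tensor = isinstance(F_in, Tensor)
    x = F_in if is_tensor else Tensor(np.asarray(F_in, dtype=np.float64))
    if x.shape[-1] != params.channels:
        raise ValueError(f"expected {params.channels} channels, got {x.shape[-1]}")
    heads = []
    for wq, wk, wv in zip(params.W_q, params.W_k, params.W_v):
        score = wq(x) @ wk(x).swapaxes(-1, -2)
        heads.append(ad.softmax(score, axis=-1) @ wv(x))
    out = params.W_o(ad.concatenate(heads, axis=-1))
    return out if is_tensor else out.data


def laplacian_enhance_mh(F_in, F_sa, params: MultiHeadParams):
    is_tensor = isinstance(F_in, Tensor)
    x = F_in if isinstance(F_in, Tensor) else Tensor(np.asarray(F_in, dtype=np.float64))
    s = F_sa if isinstance(F_sa, Tensor) else Tensor(np.asarray(F_sa, dtype=np.float64))
    out = params.lbr(x - s) + x
    return out if is_tensor else out.data
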