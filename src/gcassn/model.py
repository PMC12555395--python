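"""The full segmentation network: Trans-net alignment + stacked GCASM units.

Pipeline for an N x 3 input cloud:

1. Trans-net predicts a 3x3 transform (identity at initialization) that
   re-poses the cloud; the aligned coordinates feed the feature extractor.
2. A stack of GCASM units (graph aggregation -> self-attention -> Laplacian
   residual enhancement) produces per-point features F^1..F^L.
3. The concatenated layer features pass a shared point-wise MLP to 1024
   channels and a max-pool over points yields one global feature vector.
4. Per point, [aligned xyz || F^1..F^L || global] goes through the
   segmentation head (linear 512 -> dropout -> linear 256 -> dropout ->
   linear P) to N x P logits.

Everything is permutation-equivariant in eval mode: reordering the input
points reorders the logits identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import (AttentionParams, MultiHeadParams, attention_forward)
from .graph import (GraphBlockParams, LocalGraphSet, edge_features,
                    graph_aggregate, knn_graph, neighborhood_score)
from .nn import BatchNorm, Dropout, Linear, Module, ReLU, Sequential

__all__ = [
    "ModelConfig", "SegmentationResult", "GCASM", "TransNet", "GCASSN",
    "apply_transform", "count_parameters", "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``channels`` are the per-layer GCASM output widths (the first layer
    lifts the 3-channel coordinates; later layers keep their width).  ``k``
    counts the center itself, so k=30 means 29 true neighbors.
    """

    n_classes: int = 3
    n_gcasm_layers: int = 3
    channels: tuple[int, ...] = (64, 64, 64)
    k: int = 30
    global_dim: int = 1024
    head_dims: tuple[int, int] = (512, 256)
    dropout_rate: float = 0.5
    attn_variant: str = "gcasm"          # gcasm | general | multihead4 | multihead8
    graph_metric: str = "sq_euclidean"
    weight_sq_euclid: float = 0.7
    graph_space: str = "features"        # features (dynamic) | coords (static)
    use_transnet: bool = True
    normalize: str = "unit_sphere"

    def __post_init__(self):
        if self.n_gcasm_layers < 1:
            raise ValueError("need at least one GCASM layer")
        if len(self.channels) != self.n_gcasm_layers:
            raise ValueError("one channel width per GCASM layer")
        if any(c % 4 for c in self.channels):
            raise ValueError("channel widths must be divisible by 4")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("channels", "head_dims"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SegmentationResult:
    logits: np.ndarray       # (N, P)
    predicted: np.ndarray    # (N,) argmax labels, lowest index on ties

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "SegmentationResult":
        return cls(logits, np.argmax(logits, axis=-1))


def _make_attention(channels: int, variant: str, rng) -> Module:
    if variant in ("gcasm", "general"):
        return AttentionParams(channels, rng, variant=variant)
    if variant == "multihead4":
        return MultiHeadParams(channels, 4, rng)
    if variant == "multihead8":
        return MultiHeadParams(channels, 8, rng)
    raise ValueError(f"unknown attention variant {variant!r}")


class GCASM(Module):
    """One graph-convolution + self-attention unit."""

    def __init__(self, in_channels: int, out_channels: int, k: int,
                 rng: np.random.Generator, attn_variant: str = "gcasm",
                 graph_metric: str = "sq_euclidean",
                 weight_sq_euclid: float = 0.7,
                 graph_space: str = "features",
                 use_graph: bool = True, use_attention: bool = True):
        super().__init__()
        self.k = k
        self.graph_metric = graph_metric
        self.weight_sq_euclid = weight_sq_euclid
        self.graph_space = graph_space
        self.use_graph = use_graph
        self.use_attention = use_attention
        self.graph_params = (GraphBlockParams(in_channels, out_channels, rng)
                             if use_graph else Linear(in_channels, out_channels, rng))
        self.attn_params = (_make_attention(out_channels, attn_variant, rng)
                            if use_attention else None)

    def forward(self, F: Tensor, coords: np.ndarray | None = None) -> Tensor:
        n = F.shape[-2]
        if self.use_graph:
            if self.k > n:
                raise ValueError(f"k={self.k} exceeds the {n} available points")
            if self.graph_space == "features":
                space = F.data if isinstance(F, Tensor) else np.asarray(F)
            elif coords is not None:
                space = np.asarray(coords)
            else:
                raise ValueError("graph_space='coords' requires coordinates")
            score = neighborhood_score(space, self.graph_metric,
                                       self.weight_sq_euclid)
            idx = knn_graph(score, self.k)
            graph = LocalGraphSet(idx, edge_features(F, idx), self.k)
            F1 = graph_aggregate(F, graph, self.graph_params)
        else:
            F1 = ad.relu(self.graph_params(F))
        if self.attn_params is None:
            return F1
        return attention_forward(F1, self.attn_params)


class TransNet(Module):
    """Learned 3x3 alignment: GCASM -> MLP 1024 -> max-pool -> 512 -> 256 -> 9.

    The final 9-unit layer starts at zero and the flattened identity is
    added, so an untrained network applies exactly the identity transform.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c = config.channels[0]
        self.gcasm = GCASM(3, c, config.k, rng,
                           attn_variant=config.attn_variant,
                           graph_metric=config.graph_metric,
                           weight_sq_euclid=config.weight_sq_euclid,
                           graph_space=config.graph_space)
        self.lift = Sequential(Linear(c, config.global_dim, rng),
                               BatchNorm(config.global_dim), ReLU())
        self.head = Sequential(Linear(config.global_dim, 512, rng),
                               BatchNorm(512), ReLU(),
                               Linear(512, 256, rng),
                               BatchNorm(256), ReLU())
        final = Linear(256, 9, rng)
        final.weight.data[:] = 0.0
        final.bias.data[:] = 0.0
        self.final = final

    def forward(self, cloud: Tensor) -> Tensor:
        """(..., N, 3) -> (..., 3, 3) transform matrix."""
        feats = self.gcasm(cloud, coords=cloud.data)
        pooled = self.lift(feats).max(axis=-2)        # (..., 1024)
        nine = self.final(self.head(pooled))
        nine = nine + Tensor(np.eye(3).reshape(9))
        return nine.reshape(*nine.shape[:-1], 3, 3)


def apply_transform(cloud, M):
    """Row-vector convention: each output point is ``point @ M``."""
    if isinstance(cloud, Tensor) or isinstance(M, Tensor):
        return ad.as_tensor(cloud) @ ad.as_tensor(M)
    return np.asarray(cloud) @ np.asarray(M)


class GCASSN(Module):
    """Full segmentation network (see module docstring for the pipeline)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.transnet = TransNet(config, rng) if config.use_transnet else None
        self.gcasm_layers = []
        in_c = 3
        for c in config.channels:
            self.gcasm_layers.append(
                GCASM(in_c, c, config.k, rng,
                      attn_variant=config.attn_variant,
                      graph_metric=config.graph_metric,
                      weight_sq_euclid=config.weight_sq_euclid,
                      graph_space=config.graph_space))
            in_c = c
        total_c = sum(config.channels)
        self.fuse = Sequential(Linear(total_c, config.global_dim, rng),
                               BatchNorm(config.global_dim), ReLU())
        h1, h2 = config.head_dims
        head_in = 3 + total_c + config.global_dim
        self.head = Sequential(
            Linear(head_in, h1, rng), BatchNorm(h1), ReLU(),
            Dropout(config.dropout_rate),
            Linear(h1, h2, rng), BatchNorm(h2), ReLU(),
            Dropout(config.dropout_rate),
            Linear(h2, config.n_classes, rng))

    def reseed_dropout(self, seed: int):
        for i, m in enumerate(self.modules()):
            if isinstance(m, Dropout):
                m.reseed(seed + i)

    def forward(self, cloud) -> Tensor:
        """(..., N, 3) coordinates -> (..., N, P) logits."""
        x = cloud if isinstance(cloud, Tensor) else \
            Tensor(np.asarray(cloud, dtype=np.float64))
        if x.shape[-1] != 3:
            raise ValueError("input cloud must have 3 coordinate channels")
        if self.transnet is not None:
            M = self.transnet(x)
            aligned = apply_transform(x, M)
        else:
            aligned = x
        feats = []
        F = aligned
        for layer in self.gcasm_layers:
            F = layer(F, coords=aligned.data)
            feats.append(F)
        stacked = ad.concatenate(feats, axis=-1)            # (..., N, sum C)
        global_feat = self.fuse(stacked).max(axis=-2, keepdims=True)
        n = x.shape[-2]
        broadcast = global_feat + Tensor(np.zeros((n, 1)))   # repeat per point
        per_point = ad.concatenate([aligned, stacked, broadcast], axis=-1)
        return self.head(per_point)

    def predict(self, cloud: np.ndarray) -> SegmentationResult:
        """Eval-mode segmentation of a single (N, 3) cloud."""
        was_training = self.training
        self.eval()
        logits = self.forward(np.asarray(cloud, dtype=np.float64)).data
        if was_training:
            self.train()
        return SegmentationResult.from_logits(logits)


def count_parameters(config: ModelConfig) -> int:
    """Exact number of learnable scalars for a given architecture."""
    return GCASSN(config, seed=0).n_parameters()


# ---------------------------------------------------------------------------
# checkpoints: one .npz parameter archive + a JSON sidecar of the config
# ---------------------------------------------------------------------------

def save_checkpoint(model: GCASSN, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {"config": asdict(model.config),
               "config_hash": model.config.config_hash()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> GCASSN:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig.from_dict(sidecar["config"])
    if config.config_hash() != sidecar["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = GCASSN(config, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
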