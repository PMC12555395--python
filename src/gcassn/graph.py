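"""Graph creation block: per-point kNN local graphs and their aggregation.

Every point acts as the center of its own local graph.  The neighborhood is
scored (squared Euclidean distance by default), the k-1 closest points plus
the center form the graph, edge features are the difference vectors
``e_i = p_i - p_center``, and the block output is

    F_graph = max_k( relu( conv( [p_center || e_i] ) ) )

with ``conv`` a shared per-edge linear map (1x1 convolution) and the max an
elementwise pool over the k graph members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm, Linear, Module

__all__ = [
    "NeighborhoodScore", "LocalGraphSet", "GraphBlockParams",
    "pairwise_sq_euclidean", "neighborhood_score", "knn_graph",
    "edge_features", "graph_aggregate", "build_local_graph",
]

METRICS = ("sq_euclidean", "pearson", "cosine", "weighted")


@dataclass
class NeighborhoodScore:
    """N x N dissimilarity scores; smaller always means closer."""

    matrix: np.ndarray
    metric: str
    weight_sq_euclid: float = 0.7


@dataclass
class LocalGraphSet:
    """Per-point local graphs: column 0 of ``neighbor_idx`` is the center."""

    neighbor_idx: np.ndarray      # (..., N, K) int
    edge_feats: np.ndarray | Tensor   # (..., N, K, C)
    k: int


class GraphBlockParams(Module):
    """Shared per-edge linear map from concatenated (center || edge) rows.

    With ``normalize=True`` (the network's setting) the concatenated rows
    are batch-normalized per channel before the conv and its output is
    normalized again before the ReLU.  The input normalization matters on
    plant clouds: edge-difference features live at organ-radius scale, one
    to two orders of magnitude below the center-position features they are
    concatenated with, and without it their pathway trains far too slowly.
    ``normalize=False`` gives the bare conv+ReLU+max form.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, normalize: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.conv = Linear(2 * in_channels, out_channels, rng)
        self.bn_in = BatchNorm(2 * in_channels) if normalize else None
        self.bn_out = BatchNorm(out_channels) if normalize else None

    def forward(self, x):
        if self.bn_in is not None:
            x = self.bn_in(x)
        h = self.conv(x)
        if self.bn_out is not None:
            h = self.bn_out(h)
        return h


# ---------------------------------------------------------------------------
# neighborhood scoring
# ---------------------------------------------------------------------------

def pairwise_sq_euclidean(F: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances via |x|^2 + |y|^2 - 2 x.y.

    Works on ``(N, C)`` or batched ``(B, N, C)`` inputs.  Values are clamped
    at zero and the diagonal forced to exactly zero to absorb floating-point
    cancellation in the matrix identity.
    """
    F = np.asarray(F, dtype=np.float64)
    sq = np.sum(F * F, axis=-1)
    d2 = sq[..., :, None] + sq[..., None, :] - 2.0 * (F @ np.swapaxes(F, -1, -2))
    np.maximum(d2, 0.0, out=d2)
    idx = np.arange(F.shape[-2])
    d2[..., idx, idx] = 0.0
    return d2


def _cosine_dissimilarity(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=-1)
    zero = norms <= 1e-300
    safe = np.where(zero, 1.0, norms)
    unit = F / safe[..., None]
    sim = unit @ np.swapaxes(unit, -1, -2)
    dis = 1.0 - sim
    # zero-norm rows cannot define a direction: dissimilarity 1 to everything
    dis = np.where(zero[..., :, None] | zero[..., None, :], 1.0, dis)
    idx = np.arange(F.shape[-2])
    dis[..., idx, idx] = 0.0
    return dis


def _pearson_dissimilarity(F: np.ndarray) -> np.ndarray:
    centered = F - F.mean(axis=-1, keepdims=True)
    return _cosine_dissimilarity(centered)


def neighborhood_score(F: np.ndarray, metric: str = "sq_euclidean",
                       weight_sq_euclid: float = 0.7) -> NeighborhoodScore:
    """Score all point pairs of a feature block; smaller = closer.

    ``sq_euclidean`` is the raw squared distance; ``cosine`` and ``pearson``
    are converted to dissimilarities ``1 - similarity``; ``weighted``
    combines a per-cloud max-normalized squared distance with the cosine
    dissimilarity as ``w*d2_norm + (1-w)*(1-cos)`` so both terms live on a
    comparable [0, ~2] dissimilarity scale.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.shape[-2] < 2:
        raise ValueError("need at least two points to score a neighborhood")
    if metric == "sq_euclidean":
        m = pairwise_sq_euclidean(F)
    elif metric == "cosine":
        m = _cosine_dissimilarity(F)
    elif metric == "pearson":
        m = _pearson_dissimilarity(F)
    elif metric == "weighted":
        if not 0.0 <= weight_sq_euclid <= 1.0:
            raise ValueError("weight_sq_euclid must be in [0, 1]")
        d2 = pairwise_sq_euclidean(F)
        peak = d2.max(axis=(-2, -1), keepdims=True)
        d2n = d2 / np.where(peak > 0, peak, 1.0)
        m = weight_sq_euclid * d2n + (1.0 - weight_sq_euclid) * \
            _cosine_dissimilarity(F)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return NeighborhoodScore(m, metric, weight_sq_euclid)


def knn_graph(score, k: int) -> np.ndarray:
    """Indices of the k closest points per row, the point itself first.

    Ties are broken by ascending point index (stable sort); the center is
    always column 0 regardless of coincident points at distance zero.
    """
    matrix = score.matrix if isinstance(score, NeighborhoodScore) else np.asarray(score)
    n = matrix.shape[-1]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    m = matrix.copy()
    idx = np.arange(n)
    m[..., idx, idx] = -np.inf      # self is closer than any coincident point
    order = np.argsort(m, axis=-1, kind="stable")
    return order[..., :k]


def edge_features(F, neighbor_idx: np.ndarray):
    """Difference vectors neighbor - center, shape ``(..., N, K, C)``.

    Accepts a plain array or a :class:`Tensor` (gradients flow through the
    gather and the subtraction).
    """
    neighbor_idx = np.asarray(neighbor_idx)
    if isinstance(F, Tensor):
        n = F.shape[-2]
    else:
        F = np.asarray(F, dtype=np.float64)
        n = F.shape[-2]
    if neighbor_idx.min() < 0 or neighbor_idx.max() >= n:
        raise IndexError("neighbor index out of range")
    if isinstance(F, Tensor):
        gathered = ad.gather_neighbors(F, neighbor_idx)
        center = F.reshape(*F.shape[:-1], 1, F.shape[-1])
        return gathered - center
    return _edge_features_np(F, neighbor_idx)


def _edge_features_np(F: np.ndarray, idx: np.ndarray) -> np.ndarray:
    if F.ndim == 2:
        return F[idx] - F[:, None, :]
    b = np.arange(F.shape[0])[:, None, None]
    return F[b, idx] - F[:, :, None, :]


def build_local_graph(F, k: int, metric: str = "sq_euclidean",
                      weight_sq_euclid: float = 0.7) -> LocalGraphSet:
    """Score + kNN + edge features in one call.

    Selection (scoring and kNN) is computed on the numeric values and is not
    differentiated; edge features keep the autodiff tape when ``F`` is a
    :class:`Tensor`.
    """
    raw = F.data if isinstance(F, Tensor) else np.asarray(F, dtype=np.float64)
    score = neighborhood_score(raw, metric, weight_sq_euclid)
    idx = knn_graph(score, k)
    return LocalGraphSet(idx, edge_features(F, idx), k)


def graph_aggregate(F, graph: LocalGraphSet, params: GraphBlockParams):
    """conv + ReLU + max over the K graph members, per center point.

    Per point i the K rows ``[F[i] || e_ij]`` pass through the shared linear
    map and ReLU; the elementwise max over the K rows is the new feature of
    point i.  Returns ``(..., N, C_out)`` matching the input container type.
    """
    is_tensor = isinstance(F, Tensor)
    Ft = F if is_tensor else Tensor(np.asarray(F, dtype=np.float64))
    edges = graph.edge_feats
    if not isinstance(edges, Tensor):
        edges = Tensor(np.asarray(edges, dtype=np.float64))
    if 2 * Ft.shape[-1] != params.conv.in_features:
        raise ValueError(
            f"params expect input width {params.conv.in_features}, "
            f"features give {2 * Ft.shape[-1]}")
    k = edges.shape[-2]
    center = Ft.reshape(*Ft.shape[:-1], 1, Ft.shape[-1])
    center_tiled = center + Tensor(np.zeros((*Ft.shape[:-1], k, 1)))
    concat = ad.concatenate([center_tiled, edges], axis=-1)
    out = ad.relu(params(concat)).max(axis=-2)
    return out if is_tensor else out.data
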