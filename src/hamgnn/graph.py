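"""Cell-cell graph construction.

Modality-specific k-NN graphs (k = 20 by default) are fused through a
simplified weighted-nearest-neighbor scheme: each modality's usefulness for
a cell is scored by how much better its own neighbors predict the cell's
profile than the other modality's neighbors do, and a per-cell softmax over
the two scores gives convex modality weights. The final consensus graph is
a k = 15 nearest-neighbor graph on the per-cell weighted combination of
z-scaled modality distances.

All neighbor selection is deterministic: distance ties break toward the
lower node id.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import pairwise_distances

from .datatypes import CellGraph, ModalityWeights

__all__ = ["knn_graph", "wnn_weights", "wnn_consensus_graph", "knn_indices"]

_MAX_DENSE_NODES = 30_000  # full pairwise matrices beyond this are not supported


def _pairwise(embedding: np.ndarray, metric: str) -> np.ndarray:
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    X = np.asarray(embedding, dtype=float)
    if X.shape[0] > _MAX_DENSE_NODES:
        raise ValueError("too many cells for exact dense neighbor search")
    D = pairwise_distances(X, metric=metric)
    np.fill_diagonal(D, np.inf)  # self is never a neighbor
    return D


def _knn_from_dist(D: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k smallest with ties broken by lower column id."""
    n = D.shape[0]
    ids = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((ids, D), axis=1)  # primary key distance, secondary id
    return order[:, :k]


def knn_indices(embedding: np.ndarray, k: int, metric: str = "euclidean") -> np.ndarray:
    """(n, k) neighbor index array, deterministic under distance ties."""
    D = _pairwise(embedding, metric)
    if k >= D.shape[0]:
        raise ValueError("k must be smaller than the number of cells")
    return _knn_from_dist(D, k)


def _edges_from_neighbors(nbrs: np.ndarray) -> np.ndarray:
    n, k = nbrs.shape
    src = np.repeat(np.arange(n), k)
    dst = nbrs.ravel()
    return np.stack([src, dst], axis=1)


def knn_graph(embedding: np.ndarray, k: int, metric: str = "euclidean") -> CellGraph:
    """Union-symmetrized k-nearest-neighbor graph."""
    nbrs = knn_indices(embedding, k, metric)
    return CellGraph(embedding.shape[0], _edges_from_neighbors(nbrs))


def _prediction_error(target: np.ndarray, nbrs: np.ndarray) -> np.ndarray:
    """Per-cell error of predicting each profile as its neighbors' mean."""
    pred = target[nbrs].mean(axis=1)
    return np.linalg.norm(target - pred, axis=1)


def wnn_weights(
    rna_embed: np.ndarray,
    atac_embed: np.ndarray,
    k: int = 20,
    rna_metric: str = "euclidean",
    atac_metric: str = "cosine",
) -> ModalityWeights:
    """Per-cell modality weights by cross-modality prediction accuracy.

    For each cell and modality m, the cell's profile in m is predicted as
    the mean of its k within-modality neighbors and, separately, of its k
    neighbors taken from the *other* modality's space. The (normalized)
    error gap is passed through a softmax (an exponential kernel) to give
    weights in [0, 1] summing to 1. A modality whose own graph predicts
    profiles better than the other modality's graph earns the larger
    weight.
    """
    rna_embed = np.asarray(rna_embed, dtype=float)
    atac_embed = np.asarray(atac_embed, dtype=float)
    if rna_embed.shape[0] != atac_embed.shape[0]:
        raise ValueError("modalities must cover the same cells")
    nbr_rna = knn_indices(rna_embed, k, rna_metric)
    nbr_atac = knn_indices(atac_embed, k, atac_metric)

    scores = []
    for target, own, other in (
        (rna_embed, nbr_rna, nbr_atac),
        (atac_embed, nbr_atac, nbr_rna),
    ):
        err_within = _prediction_error(target, own)
        err_cross = _prediction_error(target, other)
        scores.append((err_cross - err_within) / (err_cross + err_within + 1e-12))
    s_rna, s_atac = scores
    e_rna, e_atac = np.exp(s_rna), np.exp(s_atac)
    w_rna = e_rna / (e_rna + e_atac)
    return ModalityWeights(w_rna=w_rna, w_atac=1.0 - w_rna)


def _zscale_rows(D: np.ndarray) -> np.ndarray:
    """Per-cell z-scaling of finite distances; keeps the diagonal at +inf."""
    finite = np.isfinite(D)
    out = np.full_like(D, np.inf)
    mu = np.where(finite, D, 0.0).sum(axis=1) / finite.sum(axis=1)
    centered = D - mu[:, None]
    sd = np.sqrt(np.where(finite, centered, 0.0) ** 2 @ np.ones(D.shape[1]) / finite.sum(axis=1))
    sd = np.where(sd > 0, sd, 1.0)
    out[finite] = (centered / sd[:, None])[finite]
    return out


def wnn_consensus_graph(
    rna_embed: np.ndarray,
    atac_embed: np.ndarray,
    weights: ModalityWeights,
    k: int = 15,
    rna_metric: str = "euclidean",
    atac_metric: str = "cosine",
) -> CellGraph:
    """Consensus k-NN graph on per-cell weighted fused distances.

    Modality distances are z-scaled per cell before fusion so Euclidean
    RNA distances and cosine ATAC distances live on a comparable scale;
    z-scaling is strictly increasing per row, so degenerate weights
    (1, 0) reproduce the single-modality graph exactly.
    """
    D_rna = _zscale_rows(_pairwise(rna_embed, rna_metric))
    D_atac = _zscale_rows(_pairwise(atac_embed, atac_metric))
    with np.errstate(invalid="ignore"):  # 0 * inf on the diagonal
        fused = weights.w_rna[:, None] * D_rna + weights.w_atac[:, None] * D_atac
    fused[~np.isfinite(fused)] = np.inf
    np.fill_diagonal(fused, np.inf)
    if k >= fused.shape[0]:
        raise ValueError("k must be smaller than the number of cells")
    nbrs = _knn_from_dist(fused, k)
    return CellGraph(fused.shape[0], _edges_from_neighbors(nbrs))
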