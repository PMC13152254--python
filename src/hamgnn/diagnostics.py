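"""Over-smoothing and energy-conservation diagnostics.

Deep message passing homogenizes node embeddings; these metrics quantify
that collapse: mean pairwise cosine similarity (feature homogenization),
Dirichlet energy over the graph (embedding smoothness; the plain
unnormalized sum over edges of squared differences), and the
inter/intra-class similarity ratio (discriminative structure). Energy
traces recorded during integration are summarized as percent drift between
the first and last step of each epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import CellGraph, PhaseState

__all__ = [
    "EnergyTrace",
    "SmoothingReport",
    "energy_drift",
    "mean_pairwise_cosine",
    "dirichlet_energy",
    "class_similarity",
    "phase_pca",
    "smoothing_report",
]

_EPS = 1e-12
DEFAULT_MAX_PAIRS = 100_000


@dataclass
class EnergyTrace:
    """Per-epoch lists of per-step scalar energies."""

    per_epoch: list = field(default_factory=list)

    def drift_percent(self) -> np.ndarray:
        out = []
        for steps in self.per_epoch:
            steps = np.asarray(steps, dtype=float)
            if steps.size < 1 or not np.all(np.isfinite(steps)):
                raise ValueError("energy trace entries must be finite and non-empty")
            h0, hl = steps[0], steps[-1]
            out.append(100.0 * abs(hl - h0) / max(abs(h0), _EPS))
        return np.asarray(out)


@dataclass
class SmoothingReport:
    mean_pairwise_cosine: float
    dirichlet_energy: float
    intra_class_sim: float
    inter_class_sim: float
    smoothness_ratio: float

    def to_dict(self) -> dict:
        return {
            "mean_pairwise_cosine": self.mean_pairwise_cosine,
            "dirichlet_energy": self.dirichlet_energy,
            "intra_class_sim": self.intra_class_sim,
            "inter_class_sim": self.inter_class_sim,
            "smoothness_ratio": self.smoothness_ratio,
        }


def energy_drift(trace: EnergyTrace) -> dict:
    """Mean and s.d. over epochs of |H_last - H_first| / |H_first| in %."""
    if not trace.per_epoch:
        raise ValueError("empty energy trace")
    d = trace.drift_percent()
    return {
        "mean_drift_percent": float(d.mean()),
        "sd_drift_percent": float(d.std(ddof=0)),
    }


def _cosine_pairs(emb: np.ndarray, pairs_i: np.ndarray, pairs_j: np.ndarray) -> np.ndarray:
    a, b = emb[pairs_i], emb[pairs_j]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    sims = np.where(denom > 0, (a * b).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    return sims


def _sample_pairs(n: int, max_pairs: int, rng: np.random.Generator):
    total = n * (n - 1) // 2
    if total <= max_pairs:
        i, j = np.triu_indices(n, k=1)
        return i, j
    # sample flattened upper-triangle positions without replacement
    flat = rng.choice(total, size=max_pairs, replace=False)
    # invert the (i, j) -> k mapping of triu order
    i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
    j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    return i, j


def mean_pairwise_cosine(
    embeddings: np.ndarray,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> float:
    """Mean cosine similarity over all (or up to ``max_pairs`` sampled)
    unordered pairs of rows. Zero rows contribute similarity 0."""
    emb = np.asarray(embeddings, dtype=float)
    n = emb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    i, j = _sample_pairs(n, max_pairs, np.random.default_rng(seed))
    return float(_cosine_pairs(emb, i, j).mean())


def dirichlet_energy(embeddings: np.ndarray, graph: CellGraph) -> float:
    """Sum over edges (i, j) of ||x_i - x_j||^2 (unnormalized form)."""
    emb = np.asarray(embeddings, dtype=float)
    if emb.shape[0] != graph.n_nodes:
        raise ValueError("embedding rows must match graph nodes")
    if graph.n_edges == 0:
        return 0.0
    diff = emb[graph.edges[:, 0]] - emb[graph.edges[:, 1]]
    return float((diff**2).sum())


def class_similarity(
    embeddings: np.ndarray,
    labels: np.ndarray,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> dict:
    """Mean cosine over same-class pairs (intra), cross-class pairs (inter),
    and their inter/intra ratio."""
    emb = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    singletons = [c for c, s in sizes.items() if s == 1]
    if singletons:
        warnings.warn(f"classes with one member contribute no intra pairs: {singletons}")
    i, j = _sample_pairs(emb.shape[0], max_pairs, np.random.default_rng(seed))
    sims = _cosine_pairs(emb, i, j)
    same = labels[i] == labels[j]
    intra = float(sims[same].mean()) if same.any() else float("nan")
    inter = float(sims[~same].mean()) if (~same).any() else float("nan")
    ratio = inter / intra if intra not in (0.0,) and np.isfinite(intra) else float("nan")
    return {"intra": intra, "inter": inter, "ratio": ratio}


def smoothing_report(
    embeddings: np.ndarray,
    graph: CellGraph,
    labels: np.ndarray,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> SmoothingReport:
    cs = class_similarity(embeddings, labels, max_pairs=max_pairs, seed=seed)
    return SmoothingReport(
        mean_pairwise_cosine=mean_pairwise_cosine(embeddings, max_pairs, seed),
        dirichlet_energy=dirichlet_energy(embeddings, graph),
        intra_class_sim=cs["intra"],
        inter_class_sim=cs["inter"],
        smoothness_ratio=cs["ratio"],
    )


def depth_sweep(
    X,
    graph: CellGraph,
    labels,
    split,
    config,
    depths=(1, 2, 4, 8),
    horizons=(0.5, 1.0, 2.0, 4.0),
    n_seeds: int = 5,
    max_pairs: int = DEFAULT_MAX_PAIRS,
):
    """Over-smoothing ablation: GCN baselines across depths vs the
    Hamiltonian model across integration horizons.

    Trains each configuration per seed, then records test accuracy and the
    smoothing metrics of the final embeddings. Returns a tidy frame with
    columns (model, depth_or_horizon, seed, metric, value).
    """
    from dataclasses import replace

    import pandas as pd

    from .train import evaluate, fit, predict

    comp, _ = labels.composite()
    _, _, test_mask = split.masks(labels.n_cells)
    rows = []

    def record(model_name, knob, seed, res):
        preds = predict(res.model, X)[0]
        acc = evaluate(preds[test_mask], comp[test_mask])["accuracy"]
        emb = res.model.embeddings(X)
        rep = smoothing_report(emb, graph, comp, max_pairs=max_pairs, seed=seed)
        vals = {"accuracy": acc, **rep.to_dict()}
        for metric, value in vals.items():
            rows.append(
                {
                    "model": model_name,
                    "depth_or_horizon": knob,
                    "seed": seed,
                    "metric": metric,
                    "value": value,
                }
            )

    for s in range(n_seeds):
        seed = config.seed + s
        for d in depths:
            cfg = replace(config, gcn_depth=int(d), seed=seed)
            res = fit("gcn_baseline", X, graph, labels, split, cfg)
            record("gcn_baseline", float(d), seed, res)
        for T in horizons:
            cfg = replace(config, horizon=(0.0, float(T)), seed=seed)
            res = fit("hgcn", X, graph, labels, split, cfg)
            record("hgcn", float(T), seed, res)
    return pd.DataFrame(rows)


def phase_pca(state: PhaseState) -> dict:
    """Top-2 principal-component scores of the concatenated (q || p) matrix
    plus explained-variance fractions; sign fixed so each component's
    largest-magnitude loading is positive."""
    Z = state.concat()
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    k = min(2, min(Z.shape))
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(Z)
    flip = np.sign(
        pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return {
        "coords": coords * flip[None, :],
        "explained_variance_fractions": pca.explained_variance_ratio_.astype(float),
    }
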