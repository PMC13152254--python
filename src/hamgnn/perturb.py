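"""Feature and edge perturbation generators and the robustness sweep.

Emulates adversarial corruption of single-cell data: a seeded fraction of
cells gets its feature vector bit-flipped (binary entries toggled,
continuous entries negated) or shifted by Gaussian noise scaled to each
feature's s.d.; the graph is corrupted by removing existing edges and
injecting the same budget of spurious non-edges. The sweep trains both
models on identically perturbed inputs across an intensity grid and
records test metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import CellGraph, LabelSet
from .model import ModelConfig
from .train import Split, evaluate, fit, predict

__all__ = ["PerturbationSpec", "perturb_features", "perturb_edges", "robustness_sweep"]


@dataclass
class PerturbationSpec:
    feature_fraction: float = 0.0
    feature_mode: str = "bitflip"  # "bitflip" | "shift" | "zero"
    shift_sigma: float = 1.0
    edge_remove_fraction: float = 0.0
    edge_add_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("feature_fraction", "edge_remove_fraction", "edge_add_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.feature_mode not in ("bitflip", "shift", "zero"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def perturb_features(X: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Corrupt a seeded uniform sample of ceil(fraction * N) cells.

    bitflip toggles entries that are exactly 0/1 and negates the rest;
    shift adds Gaussian noise with s.d. = shift_sigma * per-feature s.d.;
    zero blanks the selected rows. Unselected rows are bit-identical.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_sel = int(np.ceil(spec.feature_fraction * n))
    out = X.copy()
    if n_sel == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    sel = rng.choice(n, size=n_sel, replace=False)
    block = out[sel]
    if spec.feature_mode == "bitflip":
        binary = (block == 0.0) | (block == 1.0)
        block = np.where(binary, 1.0 - block, -block)
    elif spec.feature_mode == "shift":
        sd = X.std(axis=0, ddof=0)
        block = block + rng.normal(0.0, 1.0, size=block.shape) * (spec.shift_sigma * sd)[None, :]
    else:  # zero
        block = np.zeros_like(block)
    out[sel] = block
    return out


def perturb_edges(graph: CellGraph, spec: PerturbationSpec) -> CellGraph:
    """Remove a seeded sample of edges and add uniformly sampled non-edges.

    Exactly ceil(remove_fraction * |E|) edges are removed and
    ceil(add_fraction * |E|) new edges (no self-loops, no duplicates)
    added, so |E'| = |E| - removed + added.
    """
    m = graph.n_edges
    n = graph.n_nodes
    n_rm = int(np.ceil(spec.edge_remove_fraction * m))
    n_add = int(np.ceil(spec.edge_add_fraction * m))
    total_possible = n * (n - 1) // 2
    if n_add > total_possible - m:
        raise ValueError("not enough non-edges available to add")
    rng = np.random.default_rng(spec.seed)
    keep_idx = np.ones(m, dtype=bool)
    if n_rm:
        keep_idx[rng.choice(m, size=n_rm, replace=False)] = False
    kept = graph.edges[keep_idx]
    existing = graph.edge_set()
    new_edges = []
    seen = set()
    while len(new_edges) < n_add:
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        if i == j:
            continue
        e = (min(i, j), max(i, j))
        if e in existing or e in seen:
            continue
        seen.add(e)
        new_edges.append(e)
    edges = np.vstack([kept, np.asarray(new_edges, dtype=np.int64).reshape(-1, 2)])
    return CellGraph(n, edges)


def robustness_sweep(
    X: np.ndarray,
    graph: CellGraph,
    labels: LabelSet,
    split: Split,
    config: ModelConfig,
    intensities=(0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    n_seeds: int = 5,
    feature_mode: str = "shift",
    models: tuple[str, ...] = ("hgcn", "gcn_baseline"),
    when: str = "train",
) -> pd.DataFrame:
    """Train (or evaluate) both models under combined feature + edge
    corruption at each intensity and seed; returns tidy results.

    ``when='train'`` perturbs before training (training on noisy data);
    ``when='eval'`` trains clean once per seed and perturbs at test time.
    Each intensity applies the same fraction to features, edge removal and
    edge addition.
    """
    rows = []
    comp, _ = labels.composite()
    _, _, test_mask = split.masks(labels.n_cells)
    for seed_offset in range(n_seeds):
        seed = config.seed + seed_offset
        clean_fits = {}
        if when == "eval":
            for mode in models:
                clean_fits[mode] = fit(
                    mode, X, graph, labels, split, replace(config, seed=seed)
                )
        for intensity in intensities:
            spec = PerturbationSpec(
                feature_fraction=intensity,
                feature_mode=feature_mode,
                edge_remove_fraction=intensity,
                edge_add_fraction=intensity,
                seed=seed,
            )
            Xp = perturb_features(X, spec)
            gp = perturb_edges(graph, spec)
            for mode in models:
                if when == "train":
                    res = fit(mode, Xp, gp, labels, split, replace(config, seed=seed))
                    preds = predict(res.model, Xp)[0]
                else:
                    model = clean_fits[mode].model
                    # evaluation-time attack: rebuild propagation on the
                    # perturbed graph with trained weights
                    from .model import normalized_adjacency

                    model.S = normalized_adjacency(gp)
                    preds = predict(model, Xp)[0]
                    model.S = normalized_adjacency(graph)
                metrics = evaluate(preds[test_mask], comp[test_mask])
                rows.append(
                    {
                        "model": mode,
                        "intensity": float(intensity),
                        "seed": seed,
                        "split": "test",
                        "accuracy": metrics["accuracy"],
                        "f1_macro": metrics["f1_macro"],
                    }
                )
    return pd.DataFrame(rows)
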