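"""Seeded generators for multi-omics fixtures and community graphs.

``make_multiome`` emulates the structure of a paired snRNA + snATAC brain
cohort: a balanced grid of 8 cell types x 2 disease states, donors nested
within disease state (8 + 7 by default, mirroring a typical
case/control cohort), negative-binomial RNA counts with planted
type/state log-fold-changes and additive donor shifts, zero-inflated
Poisson peak counts with class-specific accessibility, and multiplicative
dropout. Ground-truth effect tables are returned so supervised feature
selection can be validated against the planted signal.

``make_sbm_graph`` draws a stochastic block model with Gaussian node
features, the test bed for over-smoothing and perturbation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CellGraph, LabelSet, OmicsMatrix, QCMetrics

__all__ = ["SyntheticSpec", "make_multiome", "make_sbm_graph", "sbm_labelset"]


def sbm_labelset(block_labels: np.ndarray) -> LabelSet:
    """Wrap block assignments as a LabelSet (one block = one cell type)."""
    n = len(block_labels)
    return LabelSet(
        cell_ids=[f"c{i}" for i in range(n)],
        cell_type=np.array([f"t{b}" for b in block_labels]),
        disease_state=np.array(["s0"] * n),
    )


@dataclass
class SyntheticSpec:
    """Stated world of the multiome generator.

    Effect sizes are natural-log fold changes; ``de_fraction`` of features
    carries type effects and a disjoint equal fraction carries disease
    state effects.
    """

    n_cells: int = 2000
    n_types: int = 8
    n_states: int = 2
    n_donors: int = 15  # nested in state: 8 control, 7 case by default
    rna_dim: int = 300
    atac_dim: int = 400
    de_fraction: float = 0.20
    type_lfc: float = 1.8
    state_lfc: float = 1.2
    rna_dispersion: float = 8.0  # negative-binomial size parameter
    atac_sparsity: float = 0.03  # background open-probability
    atac_open_prob: float = 0.45  # class-specific open-probability
    atac_lambda: float = 3.0  # Poisson rate for open peaks
    donor_sd: float = 0.15
    dropout_rate: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_types", "n_states", "n_donors", "rna_dim", "atac_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("de_fraction", "dropout_rate", "atac_sparsity", "atac_open_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _balanced_classes(n_cells: int, n_classes: int) -> np.ndarray:
    """Composite class per cell, balanced within one cell of exact."""
    return np.arange(n_cells) % n_classes


def make_multiome(spec: SyntheticSpec) -> dict:
    """Generate paired RNA/ATAC matrices, labels, QC metrics and truth.

    Returns a dict with keys ``rna``, ``atac`` (OmicsMatrix), ``labels``
    (LabelSet), ``qc`` (QCMetrics) and ``truth`` (DataFrame of planted
    effects: feature, modality, factor, effect).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    n_classes = spec.n_types * spec.n_states
    comp = _balanced_classes(n, n_classes)
    cell_type = comp // spec.n_states
    state = comp % spec.n_states

    # donors nested within state
    donors_per_state = [
        spec.n_donors // spec.n_states + (1 if s < spec.n_donors % spec.n_states else 0)
        for s in range(spec.n_states)
    ]
    donor = np.empty(n, dtype=np.int64)
    offset = 0
    for s in range(spec.n_states):
        cells_s = np.flatnonzero(state == s)
        donor[cells_s] = offset + rng.integers(0, donors_per_state[s], size=len(cells_s))
        offset += donors_per_state[s]

    # ---- RNA: negative binomial with planted log-fold-changes ----------
    g = spec.rna_dim
    n_de = int(round(spec.de_fraction * g))
    type_genes = np.arange(0, n_de)
    state_genes = np.arange(n_de, min(2 * n_de, g))
    base_logmu = rng.normal(np.log(2.0), 0.6, size=g)
    type_eff = np.zeros((spec.n_types, g))
    type_eff[:, type_genes] = spec.type_lfc * rng.choice(
        [-1.0, 1.0], size=(spec.n_types, len(type_genes))
    )
    state_eff = np.zeros((spec.n_states, g))
    if spec.n_states > 1:
        signs = rng.choice([-1.0, 1.0], size=len(state_genes))
        for s in range(1, spec.n_states):
            state_eff[s, state_genes] = spec.state_lfc * signs
    donor_eff = rng.normal(0.0, spec.donor_sd, size=(spec.n_donors, g))

    logmu = (
        base_logmu[None, :]
        + type_eff[cell_type]
        + state_eff[state]
        + donor_eff[donor]
    )
    mu = np.exp(logmu)
    r = spec.rna_dispersion
    rna_counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    if spec.dropout_rate > 0:
        rna_counts *= rng.random(rna_counts.shape) >= spec.dropout_rate

    # ---- ATAC: zero-inflated Poisson with class-specific accessibility -
    k = spec.atac_dim
    n_da = int(round(spec.de_fraction * k))
    type_peaks = np.arange(0, n_da)
    state_peaks = np.arange(n_da, min(2 * n_da, k))
    open_prob = np.full((n_classes, k), spec.atac_sparsity)
    # each cell type opens a characteristic subset of the type peaks
    type_assign = rng.integers(0, spec.n_types, size=len(type_peaks))
    for t in range(spec.n_types):
        peaks_t = type_peaks[type_assign == t]
        for s in range(spec.n_states):
            open_prob[t * spec.n_states + s, peaks_t] = spec.atac_open_prob
    # disease state opens/closes its peaks across all types
    state_assign = rng.integers(0, spec.n_states, size=len(state_peaks))
    for s in range(spec.n_states):
        peaks_s = state_peaks[state_assign == s]
        for t in range(spec.n_types):
            open_prob[t * spec.n_states + s, peaks_s] = spec.atac_open_prob
    opened = rng.random((n, k)) < open_prob[comp]
    atac_counts = np.where(opened, rng.poisson(spec.atac_lambda, size=(n, k)), 0).astype(float)
    if spec.dropout_rate > 0:
        atac_counts *= rng.random(atac_counts.shape) >= spec.dropout_rate

    # ---- QC metrics: ~5% of cells fail the standard ATAC thresholds ----
    ns = rng.lognormal(mean=-0.2, sigma=0.45, size=n)  # ~2-3% above 2
    tss = rng.normal(4.0, 1.0, size=n)  # ~2-3% below 2

    gene_ids = [f"gene{i:04d}" for i in range(g)]
    peak_ids = [f"peak{i:04d}" for i in range(k)]
    cell_ids = [f"cell{i:05d}" for i in range(n)]
    rna = OmicsMatrix(rna_counts, gene_ids, cell_ids, "rna")
    atac = OmicsMatrix(atac_counts, peak_ids, cell_ids, "atac")
    labels = LabelSet(
        cell_ids=cell_ids,
        cell_type=np.array([f"type{t}" for t in cell_type]),
        disease_state=np.array([f"state{s}" for s in state]),
        donor_id=np.array([f"donor{d:02d}" for d in donor]),
    )
    qc = QCMetrics(cell_ids=cell_ids, nucleosome_signal=ns, tss_enrichment=tss)

    truth_rows = []
    for j in type_genes:
        truth_rows.append({"feature": gene_ids[j], "modality": "rna", "factor": "type",
                           "effect": spec.type_lfc})
    for j in state_genes:
        truth_rows.append({"feature": gene_ids[j], "modality": "rna", "factor": "state",
                           "effect": spec.state_lfc})
    for j in type_peaks:
        truth_rows.append({"feature": peak_ids[j], "modality": "atac", "factor": "type",
                           "effect": spec.atac_open_prob - spec.atac_sparsity})
    for j in state_peaks:
        truth_rows.append({"feature": peak_ids[j], "modality": "atac", "factor": "state",
                           "effect": spec.atac_open_prob - spec.atac_sparsity})
    truth = pd.DataFrame(truth_rows)
    return {"rna": rna, "atac": atac, "labels": labels, "qc": qc, "truth": truth}


def make_sbm_graph(
    n: int = 200,
    blocks: int = 4,
    p_in: float = 0.3,
    p_out: float = 0.05,
    feature_dim: int = 16,
    seed: int = 0,
    separation: float = 0.5,
    noise_sd: float = 1.0,
) -> dict:
    """Stochastic block model with Gaussian class-mean node features.

    Returns ``{"graph": CellGraph, "X": (n, feature_dim), "labels": (n,)}``.
    """
    if p_in <= p_out:
        raise ValueError("p_in must exceed p_out")
    sizes = [n // blocks + (1 if b < n % blocks else 0) for b in range(blocks)]
    probs = [[p_in if i == j else p_out for j in range(blocks)] for i in range(blocks)]
    G = nx.stochastic_block_model(sizes, probs, seed=int(seed))
    edges = np.array([(u, v) for u, v in G.edges()], dtype=np.int64).reshape(-1, 2)
    graph = CellGraph(n, edges)
    labels = np.concatenate([[b] * s for b, s in enumerate(sizes)]).astype(np.int64)
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, 1.0, size=(blocks, feature_dim)) * separation
    X = means[labels] + rng.normal(0.0, noise_sd, size=(n, feature_dim))
    return {"graph": graph, "X": X, "labels": labels}
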