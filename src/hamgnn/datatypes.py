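"""Core in-memory containers shared across the pipeline.

The containers are deliberately light: an omics matrix is a dense or sparse
cells × features block with ids and a modality tag; a cell graph is an
undirected simple graph stored once per unordered pair. Validation happens
at construction so downstream code can assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "OmicsMatrix",
    "QCMetrics",
    "FeatureSelection",
    "CellGraph",
    "ModalityWeights",
    "LabelSet",
    "PhaseState",
]


@dataclass
class OmicsMatrix:
    """Cells × features numeric matrix with a modality tag.

    ``values`` may be a dense ndarray or a scipy sparse matrix; raw counts
    must be non-negative (checked), normalized layers may be signed (pass
    ``raw=False``).
    """

    values: np.ndarray | sp.spmatrix
    feature_ids: list[str]
    cell_ids: list[str]
    modality: str  # "rna" | "atac"
    raw: bool = True

    def __post_init__(self):
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n, f = self.values.shape
        if n != len(self.cell_ids) or f != len(self.feature_ids):
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.feature_ids)) != f:
            raise ValueError("feature_ids must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        dense_view = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense_view)):
            raise ValueError("matrix contains NaN/Inf")
        if self.raw and dense_view.size and dense_view.min() < 0:
            raise ValueError("raw counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, mask_or_idx) -> "OmicsMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        vals = self.values[idx] if not sp.issparse(self.values) else self.values[idx, :]
        return OmicsMatrix(
            vals,
            self.feature_ids,
            [self.cell_ids[i] for i in idx],
            self.modality,
            raw=self.raw,
        )

    def subset_features(self, ids: list[str]) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = np.array([pos[f] for f in ids], dtype=int)
        vals = self.values[:, idx]
        return OmicsMatrix(vals, list(ids), self.cell_ids, self.modality, raw=self.raw)


@dataclass
class QCMetrics:
    """Per-cell ATAC quality metrics."""

    cell_ids: list[str]
    nucleosome_signal: np.ndarray
    tss_enrichment: np.ndarray

    def __post_init__(self):
        self.nucleosome_signal = np.asarray(self.nucleosome_signal, dtype=float)
        self.tss_enrichment = np.asarray(self.tss_enrichment, dtype=float)
        n = len(self.cell_ids)
        if len(self.nucleosome_signal) != n or len(self.tss_enrichment) != n:
            raise ValueError("metric lengths must equal number of cells")


@dataclass
class FeatureSelection:
    """An ordered list of selected features plus the provenance needed to
    prove no test-cell leakage (the training cell ids it was derived from)."""

    selected_ids: list[str]
    method: str  # hvg_vst | wilcoxon_de | variance | mutual_info | rfe
    derived_from: set = field(default_factory=set)
    stats: dict = field(default_factory=dict)


class CellGraph:
    """Undirected, unweighted simple graph over cells.

    Edges are stored once per unordered pair as a sorted (m, 2) int array.
    """

    def __init__(self, n_nodes: int, edges):
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            if hi.max() >= n_nodes or lo.min() < 0:
                raise ValueError("edge endpoint out of range")
            canon = np.stack([lo, hi], axis=1)
            canon = np.unique(canon, axis=0)
        else:
            canon = edges.reshape(0, 2)
        self.n_nodes = int(n_nodes)
        self.edges = canon

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        if self.n_edges == 0:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.n_edges)
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )

    def edge_set(self) -> set:
        return {(int(a), int(b)) for a, b in self.edges}

    def __eq__(self, other):
        return (
            isinstance(other, CellGraph)
            and self.n_nodes == other.n_nodes
            and np.array_equal(self.edges, other.edges)
        )

    def __repr__(self):  # pragma: no cover
        return f"CellGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class ModalityWeights:
    """Per-cell convex weights over the two modalities (sum to one)."""

    w_rna: np.ndarray
    w_atac: np.ndarray

    def __post_init__(self):
        self.w_rna = np.asarray(self.w_rna, dtype=float)
        self.w_atac = np.asarray(self.w_atac, dtype=float)
        if self.w_rna.shape != self.w_atac.shape:
            raise ValueError("weight arrays must align")
        s = self.w_rna + self.w_atac
        if not np.allclose(s, 1.0, atol=1e-8):
            raise ValueError("weights must sum to 1 per cell")
        if (self.w_rna < -1e-12).any() or (self.w_atac < -1e-12).any():
            raise ValueError("weights must be non-negative")


@dataclass
class LabelSet:
    """Per-cell annotations: cell type, disease state, optional donor."""

    cell_ids: list[str]
    cell_type: np.ndarray
    disease_state: np.ndarray
    donor_id: np.ndarray | None = None

    def __post_init__(self):
        self.cell_type = np.asarray(self.cell_type)
        self.disease_state = np.asarray(self.disease_state)
        n = len(self.cell_ids)
        if len(self.cell_type) != n or len(self.disease_state) != n:
            raise ValueError("label lengths must equal number of cells")
        if self.donor_id is not None:
            self.donor_id = np.asarray(self.donor_id)
            if len(self.donor_id) != n:
                raise ValueError("donor_id length must equal number of cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def composite(self) -> tuple[np.ndarray, list[str]]:
        """Joint type × state labels as integer codes plus code names."""
        names = []
        codes = np.empty(self.n_cells, dtype=np.int64)
        lut: dict[tuple, int] = {}
        types = sorted({str(t) for t in self.cell_type})
        states = sorted({str(s) for s in self.disease_state})
        for t in types:
            for s in states:
                lut[(t, s)] = len(names)
                names.append(f"{t}|{s}")
        for i in range(self.n_cells):
            codes[i] = lut[(str(self.cell_type[i]), str(self.disease_state[i]))]
        return codes, names

    def type_codes(self) -> tuple[np.ndarray, list[str]]:
        names = sorted({str(t) for t in self.cell_type})
        lut = {t: i for i, t in enumerate(names)}
        return np.array([lut[str(t)] for t in self.cell_type]), names

    def state_codes(self) -> tuple[np.ndarray, list[str]]:
        names = sorted({str(s) for s in self.disease_state})
        lut = {s: i for i, s in enumerate(names)}
        return np.array([lut[str(s)] for s in self.disease_state]), names


@dataclass
class PhaseState:
    """Paired position/momentum embeddings, one row per cell."""

    q: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q.shape != self.p.shape:
            raise ValueError("q and p must have the same shape")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.p))):
            raise ValueError("phase state must be finite")

    def concat(self) -> np.ndarray:
        return np.concatenate([self.q, self.p], axis=1)

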