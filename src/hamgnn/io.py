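"""Readers and writers for the on-disk formats.

Matrices travel as MatrixMarket coordinate files with features.tsv /
barcodes.tsv sidecars (cells x features orientation) or as dense TSV with
a header row of feature ids and a first column of cell ids. Labels and QC
metrics are TSV; graphs are two-column 0-based integer TSV edge lists
(lexicographically sorted) with a JSON sidecar; checkpoints are npz
archives of named parameter arrays plus a JSON config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import CellGraph, LabelSet, OmicsMatrix, QCMetrics

__all__ = [
    "read_matrix",
    "write_matrix_mtx",
    "write_matrix_tsv",
    "read_labels",
    "write_labels",
    "read_qc",
    "write_qc",
    "read_graph",
    "write_graph",
    "write_embedding",
    "read_embedding",
    "save_checkpoint",
    "load_checkpoint",
]


def write_matrix_mtx(mat: OmicsMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vals = sp.coo_matrix(mat.values)
    sio.mmwrite(str(prefix) + ".mtx", vals)
    pd.Series(mat.feature_ids).to_csv(
        str(prefix) + ".features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(mat.cell_ids).to_csv(
        str(prefix) + ".barcodes.tsv", sep="\t", index=False, header=False
    )


def write_matrix_tsv(mat: OmicsMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mat.dense(), index=mat.cell_ids, columns=mat.feature_ids)
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path, modality: str, raw: bool = True) -> OmicsMatrix:
    """Read either ``<prefix>.mtx`` (+ sidecars) or a dense TSV."""
    path = str(path)
    if path.endswith(".mtx"):
        prefix = path[: -len(".mtx")]
        vals = sp.csr_matrix(sio.mmread(path))
        features = pd.read_csv(prefix + ".features.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(prefix + ".barcodes.tsv", sep="\t", header=None)[0].tolist()
        return OmicsMatrix(vals, [str(f) for f in features], [str(c) for c in cells],
                           modality, raw=raw)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
        modality,
        raw=raw,
    )


def write_labels(labels: LabelSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": labels.cell_ids,
            "cell_type": labels.cell_type,
            "disease_state": labels.disease_state,
        }
    )
    if labels.donor_id is not None:
        df["donor_id"] = labels.donor_id
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> LabelSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return LabelSet(
        cell_ids=df["cell_id"].tolist(),
        cell_type=df["cell_type"].to_numpy(),
        disease_state=df["disease_state"].to_numpy(),
        donor_id=df["donor_id"].to_numpy() if "donor_id" in df else None,
    )


def write_qc(qc: QCMetrics, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": qc.cell_ids,
            "nucleosome_signal": qc.nucleosome_signal,
            "tss_enrichment": qc.tss_enrichment,
        }
    ).to_csv(path, sep="\t", index=False)


def read_qc(path: str | Path) -> QCMetrics:
    df = pd.read_csv(path, sep="\t")
    return QCMetrics(
        cell_ids=df["cell_id"].astype(str).tolist(),
        nucleosome_signal=df["nucleosome_signal"].to_numpy(dtype=float),
        tss_enrichment=df["tss_enrichment"].to_numpy(dtype=float),
    )


def write_graph(graph: CellGraph, path: str | Path, sidecar: dict | None = None) -> None:
    path = Path(path)
    edges = graph.edges[np.lexsort((graph.edges[:, 1], graph.edges[:, 0]))]
    pd.DataFrame(edges).to_csv(path, sep="\t", index=False, header=False)
    meta = {"n_nodes": graph.n_nodes, "n_edges": graph.n_edges}
    meta.update(sidecar or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_graph(path: str | Path) -> CellGraph:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    try:
        edges = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=np.int64)
    except pd.errors.EmptyDataError:
        edges = np.zeros((0, 2), dtype=np.int64)
    return CellGraph(meta["n_nodes"], edges)


def write_embedding(emb: np.ndarray, cell_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(emb, index=cell_ids).to_csv(path, sep="\t", header=False)


def read_embedding(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


CHECKPOINT_VERSION = 1


def save_checkpoint(model, path: str | Path, extra_config: dict | None = None) -> None:
    """Single-file archive of named parameter tensors + JSON config."""
    path = Path(path)
    arrays = {p.name: p.data for p in model.params()}
    np.savez(path, **arrays)
    cfg = {
        "version": CHECKPOINT_VERSION,
        "mode": model.mode,
        "config": vars(model.config).copy(),
        "n_classes": model.n_classes,
    }
    cfg["config"]["horizon"] = list(cfg["config"]["horizon"])
    Path(str(path) + ".json").write_text(json.dumps(cfg, indent=1))


def load_checkpoint(path: str | Path, graph: CellGraph, n_features: int):
    """Rebuild a model from a checkpoint archive and its JSON sidecar."""
    from .model import ModelConfig, build_model

    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError("unsupported checkpoint version")
    cfg_dict = dict(meta["config"])
    cfg_dict["horizon"] = tuple(cfg_dict["horizon"])
    config = ModelConfig(**cfg_dict)
    n_classes = meta["n_classes"]
    model = build_model(
        meta["mode"],
        n_features,
        n_classes if len(n_classes) > 1 else n_classes[0],
        graph,
        config,
    )
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as arc:
        for p in model.params():
            p.data = arc[p.name].copy()
    return model
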