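"""High-level orchestration of the preprocessing -> graph -> model stages.

This is the programmatic counterpart of the command-line workflow: QC
filtering, per-modality normalization and embedding, training-set-only
differential feature selection, weighted-nearest-neighbor graph fusion,
model training and evaluation. Each stage draws its randomness from a
seed derived from the single run seed with a fixed per-stage counter, so
any stage can be re-run in isolation and reproduce its output bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import preprocess as pp
from .datatypes import CellGraph, LabelSet, OmicsMatrix, QCMetrics
from .graph import wnn_consensus_graph, wnn_weights
from .model import ModelConfig
from .train import Split, SplitSpec, evaluate, fit, predict, split_cells

__all__ = ["PipelineConfig", "stage_seed", "preprocess_multiome", "build_consensus_graph",
           "train_and_evaluate", "run_pipeline"]

_STAGES = {"simulate": 0, "split": 1, "preprocess": 2, "graph": 3, "train": 4,
           "perturb": 5, "diagnose": 6}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed via a fixed counter."""
    ss = np.random.SeedSequence([int(seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Knobs of the standard workflow (clamped to the data where needed)."""

    n_hvg: int = 2000
    n_lsi: int = 50
    de_alpha: float = 0.05
    feature_strategy: str = "de"  # "de" | "hvg"
    atac_features: str = "lsi"  # "lsi" | "tfidf_de"
    knn_modality: int = 20
    knn_consensus: int = 15
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)


@dataclass
class PreprocessResult:
    rna_norm: OmicsMatrix
    rna_embed: np.ndarray  # scaled HVG space, for graph construction
    atac_embed: np.ndarray  # LSI space
    tfidf: OmicsMatrix
    features: np.ndarray  # classifier input matrix
    feature_names: list
    hvg: object
    de_rna: object
    de_atac: object


def apply_qc(rna: OmicsMatrix, atac: OmicsMatrix, labels: LabelSet, qc: QCMetrics):
    """Drop cells failing ATAC QC from both modalities and the labels."""
    keep = pp.qc_filter_atac(qc)
    idx = np.flatnonzero(keep)
    lab = LabelSet(
        cell_ids=[labels.cell_ids[i] for i in idx],
        cell_type=labels.cell_type[idx],
        disease_state=labels.disease_state[idx],
        donor_id=None if labels.donor_id is None else labels.donor_id[idx],
    )
    return rna.subset_cells(idx), atac.subset_cells(idx), lab


def preprocess_multiome(
    rna: OmicsMatrix,
    atac: OmicsMatrix,
    labels: LabelSet,
    train_mask: np.ndarray,
    cfg: PipelineConfig,
) -> PreprocessResult:
    """Normalize both modalities and assemble the classifier feature matrix.

    RNA: log-normalize, select HVGs (clamped to the feature count), scale.
    ATAC: TF-IDF then LSI. Supervised selection (Wilcoxon between disease
    states, BH-adjusted) sees training cells only. The classifier matrix
    concatenates the RNA block (DE-selected or HVG, per config) with the
    ATAC block (LSI scores or DE-selected TF-IDF peaks).
    """
    rna_norm = pp.normalize_rna(rna)
    n_hvg = min(cfg.n_hvg, rna_norm.n_features)
    if n_hvg < cfg.n_hvg:
        warnings.warn(f"n_hvg clamped to feature count ({n_hvg})")
    hvg = pp.select_hvg(rna_norm, n_hvg)
    rna_embed = pp.scale_features(rna_norm.subset_features(hvg.selected_ids)).dense()

    tfidf = pp.tfidf_transform(atac)
    n_lsi = min(cfg.n_lsi, min(tfidf.values.shape) - 1)
    atac_embed = pp.lsi_reduce(tfidf, n_lsi)

    state_codes, _ = labels.state_codes()
    de_rna = pp.wilcoxon_de(rna_norm, state_codes, train_mask, alpha=cfg.de_alpha)
    de_atac = pp.wilcoxon_de(tfidf, state_codes, train_mask, alpha=cfg.de_alpha)

    if cfg.feature_strategy == "de" and de_rna.selected_ids:
        rna_block = pp.scale_features(rna_norm.subset_features(de_rna.selected_ids))
        rna_names = list(de_rna.selected_ids)
    else:
        if cfg.feature_strategy == "de":
            warnings.warn("no differential genes selected; falling back to HVG block")
        rna_block = pp.scale_features(rna_norm.subset_features(hvg.selected_ids))
        rna_names = list(hvg.selected_ids)
    if cfg.atac_features == "tfidf_de" and de_atac.selected_ids:
        atac_block = tfidf.subset_features(de_atac.selected_ids).dense()
        atac_names = list(de_atac.selected_ids)
    else:
        atac_block = atac_embed
        atac_names = [f"lsi{i}" for i in range(atac_embed.shape[1])]
    features = np.concatenate([rna_block.dense(), atac_block], axis=1)
    return PreprocessResult(
        rna_norm=rna_norm,
        rna_embed=rna_embed,
        atac_embed=atac_embed,
        tfidf=tfidf,
        features=features,
        feature_names=rna_names + atac_names,
        hvg=hvg,
        de_rna=de_rna,
        de_atac=de_atac,
    )


def build_consensus_graph(
    rna_embed: np.ndarray,
    atac_embed: np.ndarray,
    k_modality: int = 20,
    k_consensus: int = 15,
) -> tuple[CellGraph, object]:
    """Modality k-NN -> per-cell modality weights -> consensus k-NN graph."""
    w = wnn_weights(rna_embed, atac_embed, k=k_modality)
    g = wnn_consensus_graph(rna_embed, atac_embed, w, k=k_consensus)
    return g, w


def train_and_evaluate(
    X: np.ndarray,
    graph: CellGraph,
    labels: LabelSet,
    split: Split,
    config: ModelConfig,
    model_mode: str = "hgcn",
    record_energy: bool = False,
):
    """Fit one model and report metrics for each partition."""
    res = fit(model_mode, X, graph, labels, split, config, record_energy=record_energy)
    comp, _ = labels.composite()
    preds = predict(res.model, X)[0]
    target = comp if config.task == "single" else labels.type_codes()[0]
    metrics = {}
    for name, idx in (("train", split.train), ("val", split.val), ("test", split.test)):
        m = evaluate(preds[idx], target[idx])
        metrics[name] = {k: v for k, v in m.items() if k != "per_class"}
        metrics[name]["per_class"] = m["per_class"]
    return res, metrics, preds


def run_pipeline(
    rna: OmicsMatrix,
    atac: OmicsMatrix,
    labels: LabelSet,
    qc: QCMetrics | None,
    cfg: PipelineConfig,
    seed: int,
    model_mode: str = "hgcn",
):
    """QC -> split -> preprocess -> graph -> train -> metrics, end to end."""
    if qc is not None:
        rna, atac, labels = apply_qc(rna, atac, labels, qc)
    split_spec = SplitSpec(
        mode=cfg.split.mode,
        fractions=cfg.split.fractions,
        seed=stage_seed(seed, "split"),
    )
    split = split_cells(labels, split_spec)
    train_mask = split.masks(labels.n_cells)[0]
    pre = preprocess_multiome(rna, atac, labels, train_mask, cfg)
    graph, weights = build_consensus_graph(
        pre.rna_embed, pre.atac_embed, cfg.knn_modality, cfg.knn_consensus
    )
    model_cfg = ModelConfig(**{**vars(cfg.model), "seed": stage_seed(seed, "train")})
    res, metrics, preds = train_and_evaluate(
        pre.features, graph, labels, split, model_cfg, model_mode=model_mode
    )
    return {
        "labels": labels,
        "split": split,
        "preprocess": pre,
        "graph": graph,
        "weights": weights,
        "fit": res,
        "metrics": metrics,
        "preds": preds,
    }
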