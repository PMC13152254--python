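"""Shared fixtures: synthetic worlds are generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hamgnn.pipeline import (
    PipelineConfig,
    apply_qc,
    build_consensus_graph,
    preprocess_multiome,
)
from hamgnn.synthetic import SyntheticSpec, make_multiome, make_sbm_graph, sbm_labelset
from hamgnn.train import SplitSpec, split_cells


@pytest.fixture(scope="session")
def sbm_default():
    """Default 200-node, 4-block community graph with noisy features."""
    d = make_sbm_graph(seed=1)
    d["labelset"] = sbm_labelset(d["labels"])
    d["split"] = split_cells(d["labelset"], SplitSpec(seed=1))
    return d


@pytest.fixture(scope="session")
def sbm_tiny():
    """Small, fast community graph for training smoke tests."""
    d = make_sbm_graph(n=120, blocks=3, seed=3)
    d["labelset"] = sbm_labelset(d["labels"])
    d["split"] = split_cells(d["labelset"], SplitSpec(seed=3))
    return d


@pytest.fixture(scope="session")
def multiome_default():
    """The default 2,000-cell paired RNA + ATAC fixture."""
    return make_multiome(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def processed_multiome(multiome_default):
    """QC-filtered, split, preprocessed fixture plus the consensus graph."""
    d = multiome_default
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rna, atac, labels = apply_qc(d["rna"], d["atac"], d["labels"], d["qc"])
        split = split_cells(labels, SplitSpec(seed=5))
        train_mask = split.masks(labels.n_cells)[0]
        pre = preprocess_multiome(rna, atac, labels, train_mask, PipelineConfig())
        graph, weights = build_consensus_graph(pre.rna_embed, pre.atac_embed)
    return {
        "rna": rna,
        "atac": atac,
        "labels": labels,
        "split": split,
        "pre": pre,
        "graph": graph,
        "weights": weights,
        "truth": d["truth"],
    }
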