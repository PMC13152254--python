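"""Normalization, QC and feature-selection behavior, checked against hand
computations, brute-force scalar-loop oracles and (for RNA normalization)
scanpy as an independent implementation."""

import warnings

import numpy as np
import pytest

from hamgnn.datatypes import OmicsMatrix, QCMetrics
from hamgnn.preprocess import (
    lsi_reduce,
    normalize_rna,
    qc_filter_atac,
    scale_features,
    select_hvg,
    tfidf_transform,
    wilcoxon_de,
)


def om(values, modality="rna", raw=True):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return OmicsMatrix(values, [f"f{j}" for j in range(f)],
                       [f"c{i}" for i in range(n)], modality, raw=raw)


# ---------------------------------------------------------------------------
# RNA normalization and scaling
# ---------------------------------------------------------------------------


def test_normalize_rna_hand_example():
    """Row (1,1,2) at scale 10,000: counts-per-10k then log1p."""
    out = normalize_rna(om([[1, 1, 2]])).dense()
    np.testing.assert_allclose(
        out[0], [np.log(1 + 2500), np.log(1 + 2500), np.log(1 + 5000)]
    )
    assert out[0][0] == pytest.approx(7.8245, abs=1e-4)
    assert out[0][2] == pytest.approx(8.5173, abs=1e-4)


def test_normalize_rna_zero_row_and_errors():
    with pytest.warns(UserWarning, match="zero total"):
        out = normalize_rna(om([[0, 0, 0], [1, 1, 2]]))
    assert np.all(out.dense()[0] == 0)
    with pytest.raises(ValueError):
        normalize_rna(om([[1, -1]], raw=False))
    with pytest.raises(ValueError):
        normalize_rna(om([[1, 2]], modality="atac"))


def test_normalize_rna_matches_scanpy():
    import anndata
    import scanpy as sc

    counts = np.random.default_rng(0).poisson(2.0, size=(30, 20)).astype(float)
    counts[3] = 0  # scanpy leaves zero-total rows at zero too
    adata = anndata.AnnData(counts.copy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        ours = normalize_rna(om(counts)).dense()
    np.testing.assert_allclose(ours, adata.X, rtol=1e-10, atol=1e-10)


def test_scale_features_contract():
    X = scale_features(om([[1, 5], [2, 5], [3, 5]], raw=False)).dense()
    np.testing.assert_allclose(X[:, 0], np.array([-1, 0, 1]))  # sd(ddof=1) = 1
    assert np.all(X[:, 1] == 0)  # constant feature -> zeros
    rng = np.random.default_rng(1)
    Y = scale_features(om(rng.normal(size=(50, 8)), raw=False)).dense()
    np.testing.assert_allclose(Y.mean(axis=0), 0, atol=1e-8)
    np.testing.assert_allclose(Y.std(axis=0, ddof=1), 1, atol=1e-8)


def test_normalize_then_scale_commutes_with_cell_permutation():
    rng = np.random.default_rng(2)
    counts = rng.poisson(3.0, size=(25, 12)).astype(float)
    perm = rng.permutation(25)
    a = scale_features(normalize_rna(om(counts))).dense()[perm]
    b = scale_features(normalize_rna(om(counts[perm]))).dense()
    np.testing.assert_allclose(a, b, atol=1e-12)


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------


def test_select_hvg_dominant_feature_and_errors():
    # 30 features on a common mean-variance trend, one with 10x the variance
    rng = np.random.default_rng(3)
    means = rng.uniform(0.5, 4.0, size=30)
    X = np.abs(rng.normal(means, 0.1 * np.sqrt(means), size=(80, 30)))
    X[:, 7] = np.abs(rng.normal(means[7], np.sqrt(10), size=80))
    sel = select_hvg(om(X, raw=False), n_features=1)
    assert sel.selected_ids == ["f7"]
    with pytest.raises(ValueError):
        select_hvg(om(X, raw=False), n_features=31)


def test_select_hvg_permutation_invariant_and_deterministic():
    rng = np.random.default_rng(4)
    X = np.abs(rng.normal(1, 1, size=(60, 20)))
    mat = om(X, raw=False)
    sel = select_hvg(mat, 5)
    assert sel.selected_ids == select_hvg(mat, 5).selected_ids  # deterministic
    perm = rng.permutation(20)
    permuted = OmicsMatrix(X[:, perm], [f"f{j}" for j in perm],
                           mat.cell_ids, "rna", raw=False)
    sel_p = select_hvg(permuted, 5)
    assert set(sel_p.selected_ids) == set(sel.selected_ids)


# ---------------------------------------------------------------------------
# ATAC QC + TF-IDF + LSI
# ---------------------------------------------------------------------------


def test_qc_filter_thresholds():
    qc = QCMetrics(
        cell_ids=["a", "b", "c", "d"],
        nucleosome_signal=[2.5, 1.0, 2.0, np.nan],
        tss_enrichment=[3.0, 1.5, 2.0, 3.0],
    )
    with pytest.warns(UserWarning, match="NaN"):
        keep = qc_filter_atac(qc)
    # high nucleosome signal dropped; low TSS dropped; boundary kept; NaN dropped
    assert keep.tolist() == [False, False, True, False]


def test_tfidf_idf_formula_and_zeros():
    # N=2 cells, peak present in one: IDF = log(1 + 2/1) = log 3
    mat = om([[2, 0], [1, 1]], modality="atac")
    out = tfidf_transform(mat).dense()
    tf00 = 2 / 2  # cell 0 total = 2
    assert out[0, 0] == pytest.approx(np.log1p(tf00 * np.log(1 + 2 / 2)))
    assert out[0, 1] == 0.0  # zero count stays exactly zero
    idf_col1 = np.log(1 + 2 / 1)
    assert idf_col1 == pytest.approx(np.log(3), abs=1e-12)
    assert out[1, 1] == pytest.approx(np.log1p(0.5 * idf_col1))


def test_tfidf_matches_double_loop_oracle():
    rng = np.random.default_rng(5)
    X = rng.poisson(1.0, size=(20, 30)).astype(float)
    X[X < 0] = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ours = tfidf_transform(om(X, modality="atac")).dense()
    n, f = X.shape
    expected = np.zeros_like(X)
    for j in range(f):
        df = sum(1 for i in range(n) if X[i, j] > 0)
        idf = np.log(1 + n / df) if df else 0.0
        for i in range(n):
            total = X[i].sum()
            tf = X[i, j] / total if total else 0.0
            expected[i, j] = np.log(1 + tf * idf)
    np.testing.assert_allclose(ours, expected, atol=1e-10)


def test_tfidf_deterministic_bit_identical():
    X = np.random.default_rng(6).poisson(1.0, size=(15, 10)).astype(float)
    a = tfidf_transform(om(X, modality="atac")).dense()
    b = tfidf_transform(om(X, modality="atac")).dense()
    assert np.array_equal(a, b)


def test_lsi_rank_capture_and_monotonicity():
    rng = np.random.default_rng(7)
    u = rng.normal(size=(12, 1))
    v = np.abs(rng.normal(size=(1, 8)))
    rank1 = om(np.abs(u) @ v, modality="atac", raw=False)
    scores = lsi_reduce(rank1, n_components=1)
    # a rank-1 matrix is captured exactly by one component
    X = rank1.dense()
    recon_err = np.linalg.norm(X - np.outer(scores[:, 0] / np.linalg.norm(scores[:, 0]),
                                            (scores[:, 0] @ X) / np.linalg.norm(scores[:, 0])))
    assert recon_err < 1e-8

    Y = om(np.abs(rng.normal(size=(20, 10))), modality="atac", raw=False)
    errs = []
    for k in (1, 3, 5, 8):
        s = lsi_reduce(Y, k)
        # project onto the span of the scores to measure captured variance
        Q, _ = np.linalg.qr(s)
        errs.append(np.linalg.norm(Y.dense() - Q @ (Q.T @ Y.dense())))
    assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))
    with pytest.raises(ValueError):
        lsi_reduce(Y, 11)


def test_lsi_deterministic():
    Y = om(np.abs(np.random.default_rng(8).normal(size=(25, 12))),
           modality="atac", raw=False)
    assert np.array_equal(lsi_reduce(Y, 4), lsi_reduce(Y, 4))


# ---------------------------------------------------------------------------
# Wilcoxon differential selection
# ---------------------------------------------------------------------------


def _two_group_matrix(seed=9, n_per=20, f=10):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, f))
    groups = np.repeat([0, 1], n_per)
    X[groups == 1, 0] += 100.0  # fully disjoint ranges on feature 0
    X[:, 1] = 5.0  # identical constant in both groups
    return om(X, raw=False), groups


def test_wilcoxon_extreme_and_constant_features():
    mat, groups = _two_group_matrix()
    sel = wilcoxon_de(mat, groups, np.ones(40, bool), alpha=0.05)
    assert "f0" in sel.selected_ids
    assert "f1" not in sel.selected_ids


def test_wilcoxon_uses_only_train_cells():
    mat, groups = _two_group_matrix()
    train = np.zeros(40, bool)
    train[:15] = True
    train[20:35] = True
    sel = wilcoxon_de(mat, groups, train, alpha=0.05)
    corrupted = mat.dense().copy()
    corrupted[~train] = np.random.default_rng(0).normal(1e6, 1e6, size=corrupted[~train].shape)
    sel2 = wilcoxon_de(om(corrupted, raw=False), groups, train, alpha=0.05)
    assert sel.selected_ids == sel2.selected_ids
    assert sel.derived_from == {f"c{i}" for i in np.flatnonzero(train)}


def test_wilcoxon_errors():
    mat, groups = _two_group_matrix()
    with pytest.raises(ValueError):
        wilcoxon_de(mat, groups, groups == 0, alpha=0.05)  # one group absent
    with pytest.raises(ValueError):
        wilcoxon_de(mat, np.zeros(40, int), np.ones(40, bool))


def test_wilcoxon_null_fdr_control():
    """Label permutation: average selections stay near alpha * F."""
    rng = np.random.default_rng(10)
    X = om(rng.normal(size=(60, 40)), raw=False)
    counts = []
    for _ in range(50):
        groups = rng.permutation(np.repeat([0, 1], 30))
        sel = wilcoxon_de(X, groups, np.ones(60, bool), alpha=0.05)
        counts.append(len(sel.selected_ids))
    assert np.mean(counts) <= 0.05 * 40
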