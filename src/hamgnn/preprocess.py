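"""Modality-specific normalization, QC and feature selection.

RNA counts go through library-size log-normalization (counts-per-10k,
log1p), per-gene standardization, and variance-stabilized highly-variable
gene ranking. ATAC peak counts go through nucleosome-signal / TSS QC,
TF-IDF weighting and latent semantic indexing (truncated SVD). Supervised
feature selection uses two-sided Wilcoxon rank-sum tests restricted to
training cells with Benjamini-Hochberg correction, so validation and test
cells can never influence the selected feature set.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.decomposition import TruncatedSVD
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureSelection, OmicsMatrix, QCMetrics

__all__ = [
    "normalize_rna",
    "scale_features",
    "select_hvg",
    "qc_filter_atac",
    "tfidf_transform",
    "lsi_reduce",
    "wilcoxon_de",
]


def normalize_rna(counts: OmicsMatrix, scale_factor: float = 10_000.0) -> OmicsMatrix:
    """Library-size normalize to ``scale_factor`` counts per cell, then log1p.

    Cells with zero total counts come out as all-zero rows (with a warning):
    dropping cells is an explicit QC decision, not a side effect.
    """
    if counts.modality != "rna":
        raise ValueError("normalize_rna expects an RNA matrix")
    X = counts.dense()
    if X.size and X.min() < 0:
        raise ValueError("negative entries in count matrix")
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero total counts")
    safe = np.where(zero, 1.0, totals)
    out = np.log1p(X / safe[:, None] * scale_factor)
    out[zero] = 0.0
    return OmicsMatrix(out, counts.feature_ids, counts.cell_ids, "rna", raw=False)


def scale_features(X: OmicsMatrix) -> OmicsMatrix:
    """Center each feature at 0 and scale to unit sample s.d. (ddof=1).

    Constant features map to all-zero columns.
    """
    V = X.dense().astype(float)
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.zeros(V.shape[1])
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = (V - mean) / sd_safe
    out[:, sd == 0] = 0.0
    return OmicsMatrix(out, X.feature_ids, X.cell_ids, X.modality, raw=False)


def _vst_standardized_variance(X: np.ndarray) -> np.ndarray:
    """Residual-standardized variance after a mean-variance trend fit.

    A second-degree polynomial is fit to log10(variance) vs log10(mean) over
    non-constant features; counts standardized by the fitted (technical)
    s.d. are clipped at sqrt(N) before the final variance, mirroring
    variance-stabilizing HVG selection.
    """
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    stat = np.zeros(X.shape[1])
    ok = (var > 0) & (mean > 0)
    if ok.sum() >= 3:
        lm, lv = np.log10(mean[ok]), np.log10(var[ok])
        coef = np.polyfit(lm, lv, deg=2)
        fitted_sd = np.sqrt(10 ** np.polyval(coef, lm))
    elif ok.any():
        fitted_sd = np.sqrt(var[ok])
    else:
        return stat
    Z = (X[:, ok] - mean[ok]) / fitted_sd
    Z = np.clip(Z, -np.sqrt(n), np.sqrt(n))
    stat[ok] = Z.var(axis=0, ddof=1)
    return stat


def select_hvg(X: OmicsMatrix, n_features: int = 2000) -> FeatureSelection:
    """Top ``n_features`` highly-variable features by vst-style ranking.

    Deterministic: ties broken by feature order in the input matrix.
    """
    if n_features > X.n_features:
        raise ValueError("n_features exceeds the number of features")
    stat = _vst_standardized_variance(X.dense())
    # stable sort on negated statistic -> ties resolved by input order
    order = np.argsort(-stat, kind="stable")[:n_features]
    ids = [X.feature_ids[i] for i in order]
    return FeatureSelection(
        selected_ids=ids,
        method="hvg_vst",
        derived_from=set(X.cell_ids),
        stats={"standardized_variance": {X.feature_ids[i]: float(stat[i]) for i in order}},
    )


def qc_filter_atac(qc: QCMetrics) -> np.ndarray:
    """Keep-mask: cells with nucleosome signal > 2 or TSS enrichment < 2 are
    dropped (strict inequalities; boundary cells at exactly 2 are kept).
    NaN metrics drop the cell with a warning."""
    ns, tss = qc.nucleosome_signal, qc.tss_enrichment
    bad_nan = ~(np.isfinite(ns) & np.isfinite(tss))
    if bad_nan.any():
        warnings.warn(f"{int(bad_nan.sum())} cells dropped for NaN QC metrics")
    with np.errstate(invalid="ignore"):
        keep = (ns <= 2.0) & (tss >= 2.0)
    keep[bad_nan] = False
    return keep


def tfidf_transform(peaks: OmicsMatrix) -> OmicsMatrix:
    """TF-IDF weighting of peak counts in the log1p dialect.

    TF is the within-cell frequency (count / cell total), IDF_j =
    log(1 + N/df_j) with df_j the number of cells in which peak j is open,
    and the output is log(1 + TF * IDF) so structural zeros stay exactly 0.
    Peaks open in no cell give all-zero columns; zero-total cells give
    zero rows with a warning.
    """
    if peaks.modality != "atac":
        raise ValueError("tfidf_transform expects an ATAC matrix")
    X = peaks.dense().astype(float)
    if X.size and X.min() < 0:
        raise ValueError("negative entries in peak matrix")
    totals = X.sum(axis=1)
    zero_cells = totals == 0
    if zero_cells.any():
        warnings.warn(f"{int(zero_cells.sum())} cells have zero total accessibility")
    safe = np.where(zero_cells, 1.0, totals)
    tf = X / safe[:, None]
    df = (X > 0).sum(axis=0)
    n = X.shape[0]
    idf = np.where(df > 0, np.log(1.0 + n / np.maximum(df, 1)), 0.0)
    out = np.log1p(tf * idf[None, :])
    return OmicsMatrix(out, peaks.feature_ids, peaks.cell_ids, "atac", raw=False)


def lsi_reduce(tfidf: OmicsMatrix, n_components: int = 50) -> np.ndarray:
    """Latent semantic indexing: truncated SVD scores ``U @ diag(s)``.

    Uses the deterministic ARPACK solver; each component's sign is fixed so
    its largest-magnitude feature loading is positive.
    """
    X = tfidf.values if sp.issparse(tfidf.values) else tfidf.dense()
    max_rank = min(X.shape) - 1
    if n_components > min(X.shape) or n_components < 1:
        raise ValueError("n_components must be in [1, min(cells, features)]")
    if n_components > max_rank:
        # ARPACK needs k < min(shape); fall back to exact dense SVD
        U, s, Vt = np.linalg.svd(np.asarray(X if not sp.issparse(X) else X.todense()), full_matrices=False)
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    else:
        svd = TruncatedSVD(n_components=n_components, algorithm="arpack", random_state=0)
        scores = svd.fit_transform(X)
        U = scores / np.where(svd.singular_values_ > 0, svd.singular_values_, 1.0)
        s, Vt = svd.singular_values_, svd.components_
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return (U * s[None, :]) * flip[None, :]


def wilcoxon_de(
    X: OmicsMatrix,
    groups: np.ndarray,
    train_mask: np.ndarray,
    alpha: float = 0.05,
) -> FeatureSelection:
    """Two-group Wilcoxon rank-sum feature selection on training cells only.

    Two-sided asymptotic Mann-Whitney U per feature, Benjamini-Hochberg
    adjustment, selection at adjusted p < ``alpha``. Only cells under
    ``train_mask`` ever touch the statistic; the returned object records
    those cell ids.
    """
    groups = np.asarray(groups)
    train_mask = np.asarray(train_mask, dtype=bool)
    V = X.dense()[train_mask]
    g = groups[train_mask]
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("wilcoxon_de requires exactly two groups among train cells")
    a = V[g == levels[0]]
    b = V[g == levels[1]]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("one group is empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features produce benign warnings
        res = mannwhitneyu(a, b, axis=0, method="asymptotic", alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    # identical constant features: no separation, never selected
    constant = np.all(V == V[0:1, :], axis=0) if V.shape[0] else np.ones(V.shape[1], bool)
    pvals[constant] = 1.0
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    keep = padj < alpha
    order = np.argsort(padj, kind="stable")
    ids = [X.feature_ids[i] for i in order if keep[i]]
    train_ids = {X.cell_ids[i] for i in np.flatnonzero(train_mask)}
    return FeatureSelection(
        selected_ids=ids,
        method="wilcoxon_de",
        derived_from=train_ids,
        stats={
            "alpha": alpha,
            "n_train": int(train_mask.sum()),
            "padj": {X.feature_ids[i]: float(padj[i]) for i in range(len(padj))},
        },
    )
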