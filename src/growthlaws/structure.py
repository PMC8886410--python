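"""Unsupervised structure of expression matrices.

Hierarchical clustering of gene z-score profiles (Euclidean distance, Ward
linkage in the ward.D2 convention), SVD-based principal component analysis
with a per-gene PC1 variance fraction, classification of condition-specific
expression modes from PC1 (the WFSP-type split), and barcode statistics
(median-based directed lengths of per-condition deviations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .containers import as_frame

__all__ = [
    "ClusterAssignment",
    "hierarchical_clusters",
    "PCAResult",
    "pca_structure",
    "wfsp_classify",
    "BarcodeMatrix",
    "barcode_lengths",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene_id -> cluster label 1..k
    linkage: np.ndarray  # scipy linkage matrix (merge heights in column 2)
    k: int


def hierarchical_clusters(z_matrix, k: int) -> ClusterAssignment:
    """Ward-linkage clustering of gene rows, cut into k clusters.

    scipy's ``ward`` on raw observations reproduces the ward.D2 criterion on
    Euclidean distances (squared distances inside the Lance-Williams update,
    Euclidean merge heights).
    """
    df = as_frame(z_matrix)
    if df.isna().any().any():
        raise ValueError("clustering requires a complete matrix")
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(df):
        raise ValueError(f"k={k} exceeds the number of genes ({len(df)})")
    link = hierarchy.linkage(df.to_numpy(dtype=float), method="ward")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=df.index, name="cluster"), linkage=link, k=k
    )


@dataclass
class PCAResult:
    gene_scores: pd.DataFrame  # genes x PCs (U * s)
    sample_pattern: pd.DataFrame  # samples x PCs (right singular vectors)
    variance_explained: np.ndarray  # fraction of total variance per PC
    pc1_fraction: pd.Series  # per-gene fraction of variance captured by PC1

    def reconstruct(self, n_pcs: int | None = None) -> pd.DataFrame:
        """Rank-n reconstruction of the input matrix from the leading PCs."""
        n = self.gene_scores.shape[1] if n_pcs is None else n_pcs
        x = self.gene_scores.iloc[:, :n].to_numpy() @ self.sample_pattern.iloc[:, :n].to_numpy().T
        return pd.DataFrame(x, index=self.gene_scores.index, columns=self.sample_pattern.index)


def pca_structure(z_matrix) -> PCAResult:
    """SVD-based PCA with genes as observations.

    Input rows are z-scores (already centered), so no further centering is
    applied and the per-gene PC1 variance fraction is
    1 - ||z_i - zhat_i||^2 / ||z_i||^2 with zhat_i the rank-1 PC1
    reconstruction, equal to score_i1^2 / ||z_i||^2.

    Sign convention: each PC is oriented so that the sample-pattern entry of
    largest magnitude is positive (PCA signs are otherwise arbitrary; a
    deterministic rule makes downstream labels reproducible).
    """
    df = as_frame(z_matrix)
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if df.isna().any().any():
        raise ValueError("PCA requires a complete matrix")
    x = df.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # orient: largest-|entry| sample coordinate of each PC is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s[None, :]
    var_explained = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    row_norm2 = np.sum(x**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc1_frac = np.where(row_norm2 > 0, scores[:, 0] ** 2 / row_norm2, 0.0)
    pcs = [f"PC{i + 1}" for i in range(s.size)]
    return PCAResult(
        gene_scores=pd.DataFrame(scores, index=df.index, columns=pcs),
        sample_pattern=pd.DataFrame(vt.T, index=df.columns, columns=pcs),
        variance_explained=var_explained,
        pc1_fraction=pd.Series(pc1_frac, index=df.index, name="pc1_fraction"),
    )


def wfsp_classify(z_matrix, pca: PCAResult, frac_threshold: float = 0.5) -> pd.Series:
    """Label genes by their response to the first principal component.

    ``plus`` if more than ``frac_threshold`` of a gene's variance is
    explained by PC1 and its profile correlates positively with the PC1
    sample pattern, ``minus`` for negative correlation, ``none`` otherwise.
    """
    df = as_frame(z_matrix)
    v1 = pca.sample_pattern.iloc[:, 0].reindex(df.columns).to_numpy()
    x = df.to_numpy(dtype=float)
    v1c = v1 - v1.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(v1c)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = xc @ v1c / denom
    frac = pca.pc1_fraction.reindex(df.index).to_numpy()
    labels = np.full(len(df), "none", dtype=object)
    labels[(frac > frac_threshold) & (corr > 0)] = "plus"
    labels[(frac > frac_threshold) & (corr < 0)] = "minus"
    return pd.Series(labels, index=df.index, name="wfsp")


@dataclass
class BarcodeMatrix:
    x: pd.DataFrame  # per-condition replicate medians, genes x conditions
    overall_median: pd.Series  # M_i per gene
    lengths: pd.DataFrame  # capped directed lengths l_ij
    undefined: pd.Series  # genes with overall median 0 (l undefined)


def barcode_lengths(
    mass_fraction_matrix,
    design: pd.DataFrame,
    cap: tuple[float, float] = (-1.0, 2.0),
) -> BarcodeMatrix:
    """Directed barcode lengths l = (x - M)/M per gene and condition.

    x is the median mass fraction over the replicates of a condition, M the
    median over all samples; missing data are imputed to zero before the
    medians and l is clamped to ``cap``.  Genes with M = 0 are flagged (l
    undefined, returned as NaN).
    """
    df = as_frame(mass_fraction_matrix).fillna(0.0)
    cond = design.set_index("sample_id")["condition"].reindex(df.columns)
    if cond.isna().any():
        raise KeyError("matrix has samples absent from the sample sheet")
    x = df.T.groupby(cond.values).median().T
    overall = df.median(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        l = x.sub(overall, axis=0).div(overall, axis=0)
    undefined = overall == 0.0
    l.loc[undefined] = np.nan
    l = l.clip(lower=cap[0], upper=cap[1])
    return BarcodeMatrix(x=x, overall_median=overall, lengths=l, undefined=undefined)
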