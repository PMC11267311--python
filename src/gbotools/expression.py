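"""Sample-level pseudo-bulk comparisons.

Per-sample profiles are built by summing raw counts over each sample's cells
and scaling to counts-per-million before a log2(x+1) transform. On those
profiles the module provides PCA, transcriptome-distance hierarchical
clustering (1 - Pearson, average linkage) and Spearman correlation mapping
of samples onto user-supplied reference expression panels (developmental
stages, brain regions, ...), reporting each sample's best-matching reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

from .matrix import CountMatrix


def aggregate_pseudobulk(
    matrix: CountMatrix, samples: np.ndarray | None = None
) -> pd.DataFrame:
    """Sum counts per sample, scale to CPM, log2(x+1). Genes x samples."""
    labels = samples if samples is not None else matrix.samples
    if labels is None:
        raise ValueError("no sample labels on matrix and none provided")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != matrix.n_cells or any(l is None for l in labels):
        raise ValueError("every cell must carry a sample label")
    out = {}
    for name in pd.unique(labels):
        cols = np.flatnonzero(labels == name)
        total = np.asarray(matrix.counts[:, cols].sum(axis=1)).ravel().astype(float)
        depth = total.sum()
        if depth == 0:
            raise ValueError(f"sample {name!r} has zero total counts")
        out[name] = np.log2(total / depth * 1e6 + 1.0)
    return pd.DataFrame(out, index=matrix.genes)


def pca(
    pseudobulk: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered SVD of samples x genes; returns (coordinates, variance fractions)."""
    X = pseudobulk.to_numpy().T  # samples x genes
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :n_components] * s[:n_components]
    var = s**2 / (n_samples - 1)
    frac = var / max(Xc.var(axis=0, ddof=1).sum(), np.finfo(float).tiny)
    cols = [f"PC{i+1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=pseudobulk.columns, columns=cols), frac[:n_components]


@dataclass
class DistanceResult:
    distance: pd.DataFrame
    linkage: np.ndarray

    def cut(self, n_clusters: int) -> pd.Series:
        labels = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.distance.index, name="cluster")


def distance_cluster(pseudobulk: pd.DataFrame) -> DistanceResult:
    """Transcriptome distance 1 - Pearson r between samples, average linkage."""
    X = pseudobulk.to_numpy().T
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = pseudobulk.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"sample {bad!r} has a constant profile (zero variance)")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    dm = pd.DataFrame(dist, index=pseudobulk.columns, columns=pseudobulk.columns)
    return DistanceResult(distance=dm, linkage=Z)


@dataclass
class CorrelationMap:
    rho: pd.DataFrame  # samples x references
    best_match: pd.Series
    n_genes_used: int


def correlate_to_reference(
    pseudobulk: pd.DataFrame,
    panel: pd.DataFrame,
    min_shared_genes: int = 50,
    top_k_variable: int | None = None,
) -> CorrelationMap:
    """Spearman correlation of each sample against each reference column.

    Correlations use the genes shared between query and panel, optionally
    restricted to the panel's ``top_k_variable`` most variable genes. The
    best match per sample is the reference with maximal rho.
    """
    shared = pseudobulk.index.intersection(panel.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= {min_shared_genes}"
        )
    sub_panel = panel.loc[shared]
    if top_k_variable is not None:
        var = sub_panel.var(axis=1)
        shared = var.nlargest(min(top_k_variable, len(var))).index
        sub_panel = sub_panel.loc[shared]
    query = pseudobulk.loc[shared]
    rho = np.zeros((query.shape[1], sub_panel.shape[1]))
    for i, sc in enumerate(query.columns):
        for j, rc in enumerate(sub_panel.columns):
            rho[i, j] = scipy.stats.spearmanr(
                query[sc].to_numpy(), sub_panel[rc].to_numpy()
            ).statistic
    rho_df = pd.DataFrame(rho, index=query.columns, columns=sub_panel.columns)
    best = rho_df.idxmax(axis=1).rename("best_match")
    return CorrelationMap(rho=rho_df, best_match=best, n_genes_used=len(shared))
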