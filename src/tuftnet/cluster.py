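"""Graph-based cell clustering with a similarity-driven merge rule.

Workflow: variance-stabilised highly-variable-gene selection, PCA, shared
nearest-neighbour (Jaccard) graph, Louvain community detection at a given
resolution, then merging of cluster pairs separated by fewer than 30 genes
at a two-sided ROC AUC of 0.6.
"""

from __future__ import annotations

import random as _random

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from tuftnet.markers import auc_test

__all__ = [
    "standardized_variance",
    "select_hvg",
    "embed_pca",
    "snn_graph",
    "find_clusters",
    "merge_similar_clusters",
    "default_k",
]


def default_k(n_cells: int, k_max: int = 250, cells_per_neighbor: int = 20) -> int:
    """Neighbourhood size scaled to cohort size: min(k_max, n_cells // 20)."""
    return max(2, min(k_max, n_cells // cells_per_neighbor))


def standardized_variance(X, frac: float = 0.3) -> np.ndarray:
    """Variance-stabilised per-gene variance (clipped standardised counts).

    A lowess curve of log10(variance) on log10(mean) gives each gene an
    expected standard deviation; counts are standardised by it, clipped at
    sqrt(n_cells), and the variance of the clipped values is returned.
    Genes with zero variance score 0.
    """
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    out = np.zeros(X.shape[1])
    ok = (var > 0) & (mean > 0)
    if ok.sum() < 3:
        return out
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    fit = lowess(ly, lx, frac=frac, xvals=lx)
    sd_exp = np.sqrt(10.0 ** fit)
    clip = np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X[:, ok] - mean[ok]) / sd_exp
        np.clip(Z, -clip, clip, out=Z)
        out[ok] = Z.var(axis=0, ddof=1)
    out[~np.isfinite(out)] = 0.0
    return out


def select_hvg(X, gene_names, n: int = 5000) -> list[str]:
    """Top-n genes by standardised variance; ties broken by gene order."""
    gene_names = list(gene_names)
    if n > len(gene_names):
        raise ValueError("n exceeds number of genes")
    sv = standardized_variance(X)
    order = np.lexsort((np.arange(len(gene_names)), -sv))
    return [gene_names[i] for i in order[:n]]


def embed_pca(X, n_pcs: int = 50, scale: bool = True, seed: int = 0) -> np.ndarray:
    """PCA scores of centred (optionally unit-scaled) expression.

    Component signs are fixed by making each loading's largest-magnitude
    entry positive, so results are deterministic up to numerical noise.
    """
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    solver = "arpack" if n_pcs < min(X.shape) else "full"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(X)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def snn_graph(scores: np.ndarray, k: int, prune: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbour graph weighted by Jaccard overlap of kNN sets.

    Each cell's neighbour set includes itself; self-edges are excluded and
    edges with Jaccard weight below ``prune`` (default 1/15, the common
    SNN pruning cutoff) are dropped. Pass ``prune=0`` to keep every edge
    with positive overlap.
    """
    n = scores.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self at distance 0
    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix((np.ones(rows.size, dtype=np.int32),
                       (rows, idx.ravel())), shape=(n, n))
    inter = (A @ A.T).tocoo()
    mask = inter.row < inter.col
    r, c, i = inter.row[mask], inter.col[mask], inter.data[mask].astype(float)
    jac = i / (2 * (k + 1) - i)
    keep = jac > max(prune, 0)
    edges = np.column_stack([r[keep], c[keep]])
    g = igraph.Graph(n=n, edges=edges.tolist(),
                     edge_attrs={"weight": jac[keep].tolist()})
    return g


def find_clusters(graph: igraph.Graph, resolution: float = 0.6,
                  seed: int = 0) -> np.ndarray:
    """Louvain communities on the weighted SNN graph, relabelled by size."""
    state = _random.getstate()
    try:
        igraph.set_random_number_generator(_random)
        _random.seed(seed)
        part = graph.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _random.setstate(state)
    labels = np.asarray(part.membership)
    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    sizes = pd.Series(labels).value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index)}
    return np.asarray([mapping[v] for v in labels])


def count_de_genes(logtp, labels, a, b, auc_threshold: float = 0.6) -> int:
    """Genes separating clusters a and b at two-sided AUC >= threshold."""
    auc = auc_test(logtp, np.asarray(labels) == a, np.asarray(labels) == b)
    return int(np.sum(np.maximum(auc, 1 - auc) >= auc_threshold))


def merge_similar_clusters(labels, logtp, auc_threshold: float = 0.6,
                           min_de_genes: int = 30) -> np.ndarray:
    """Iteratively merge cluster pairs with < min_de_genes AUC-discriminating genes.

    At each pass the pair with the fewest discriminating genes (below the
    cutoff) is merged; merging stops when every remaining pair is separated
    by at least ``min_de_genes`` genes. Labels are returned contiguous,
    ordered by cluster size.
    """
    labels = np.asarray(labels).copy()
    while True:
        ids = np.unique(labels)
        if ids.size < 2:
            break
        best, best_count = None, min_de_genes
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                cnt = count_de_genes(logtp, labels, a, b, auc_threshold)
                if cnt < best_count:
                    best, best_count = (a, b), cnt
        if best is None:
            break
        a, b = best
        labels[labels == b] = a
    return _relabel_by_size(labels)
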