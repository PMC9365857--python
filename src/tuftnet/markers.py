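"""Cluster marker statistics: log-TP10K, two-part hurdle test, ROC AUC.

The marker test contrasts one cluster against all other cells with a
two-part (hurdle) likelihood-ratio test: a binomial component for the
detection rate (expression > 0) and a Gaussian component for the mean of
positive log-TP10K values, combined as a chi-square with 2 degrees of
freedom. Reported per gene: p_val, avg_log2FC, pct.1, pct.2 and a
Bonferroni-adjusted p_val_adj = min(1, p_val * n_genes_tested).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import chi2, rankdata

__all__ = ["log_tp10k", "hurdle_marker_test", "auc_test"]


def log_tp10k(X, scale: float = 1e4):
    """ln(count / cell_total * scale + 1), per cell.

    Accepts a dense array, sparse matrix or AnnData; returns the same kind
    (sparse in, sparse out).
    """
    if isinstance(X, AnnData):
        return log_tp10k(X.X, scale=scale)
    if sp.issparse(X):
        X = sp.csr_matrix(X, dtype=float)
        totals = np.asarray(X.sum(axis=1)).ravel()
        totals[totals == 0] = 1.0
        out = X.multiply(scale / totals[:, None]).tocsr()
        out.data = np.log1p(out.data)
        return out
    X = np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals[:, None] * scale)


def _binomial_lrt(d1: np.ndarray, n1: int, d2: np.ndarray, n2: int) -> np.ndarray:
    """Vectorised 2x2 binomial LRT chi-square (detection-rate component)."""

    def ll(d, n):
        d = d.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(d > 0, d * np.log(d / n), 0.0)
            t2 = np.where(n - d > 0, (n - d) * np.log(1 - d / n), 0.0)
        return t1 + t2

    pooled = ll(d1 + d2, n1 + n2)
    return np.maximum(2.0 * (ll(d1, n1) + ll(d2, n2) - pooled), 0.0)


def _gaussian_lrt(s1, ss1, n1, s2, ss2, n2):
    """Vectorised equal-variance Gaussian mean LRT from sums/sums of squares."""
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(n1 > 0, s1 / np.maximum(n1, 1), 0.0)
        m2 = np.where(n2 > 0, s2 / np.maximum(n2, 1), 0.0)
        m = (s1 + s2) / np.maximum(n, 1)
        ss_full = (ss1 - n1 * m1**2) + (ss2 - n2 * m2**2)
        ss_null = (ss1 + ss2) - n * m**2
        ok = (n1 > 0) & (n2 > 0) & (ss_full > 0)
        stat = np.where(ok, n * np.log(np.maximum(ss_null, 1e-300) /
                                       np.maximum(ss_full, 1e-300)), 0.0)
    return np.maximum(stat, 0.0)


def hurdle_marker_test(logtp, labels, cluster_id, gene_names=None) -> pd.DataFrame:
    """Markers of one cluster versus all other cells combined.

    ``logtp`` is a cells x genes log-TP10K matrix (dense or sparse).
    Returns a DataFrame indexed by gene with columns ``p_val``,
    ``avg_log2FC``, ``pct.1``, ``pct.2``, ``p_val_adj``, sorted by p_val.
    """
    labels = np.asarray(labels)
    in_mask = labels == cluster_id
    if in_mask.sum() == 0:
        raise ValueError(f"cluster {cluster_id!r} absent from labels")
    if in_mask.sum() < 3:
        raise ValueError("cluster must have at least 3 cells")
    if sp.issparse(logtp):
        M = sp.csr_matrix(logtp, dtype=float)
        A, B = M[in_mask], M[~in_mask]

        def stats(part):
            d = np.asarray((part > 0).sum(axis=0)).ravel()
            s = np.asarray(part.sum(axis=0)).ravel()
            ss = np.asarray(part.multiply(part).sum(axis=0)).ravel()
            em = np.asarray(part.expm1().sum(axis=0)).ravel() / part.shape[0]
            return d, s, ss, em

    else:
        M = np.asarray(logtp, dtype=float)
        A, B = M[in_mask], M[~in_mask]

        def stats(part):
            d = (part > 0).sum(axis=0)
            s = part.sum(axis=0)
            ss = (part**2).sum(axis=0)
            em = np.expm1(part).sum(axis=0) / part.shape[0]
            return d, s, ss, em

    d1, s1, ss1, em1 = stats(A)
    d2, s2, ss2, em2 = stats(B)
    n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
    stat = _binomial_lrt(d1, n1, d2, n2) + _gaussian_lrt(s1, ss1, d1, s2, ss2, d2)
    p = chi2.sf(stat, df=2)
    G = M.shape[1]
    if gene_names is None:
        gene_names = [f"gene{i}" for i in range(G)]
    out = pd.DataFrame(
        {
            "p_val": p,
            "avg_log2FC": np.log2(em1 + 1) - np.log2(em2 + 1),
            "pct.1": d1 / n1,
            "pct.2": d2 / n2,
            "p_val_adj": np.minimum(1.0, p * G),
        },
        index=pd.Index(gene_names, name="gene"),
    )
    return out.sort_values("p_val", kind="mergesort")


def auc_test(values, group1_mask, group2_mask=None) -> np.ndarray:
    """Per-gene Mann-Whitney AUC of group 1 versus group 2, midrank ties.

    ``values`` is cells x genes (dense or sparse). With ``group2_mask``
    omitted, group 2 is the complement of group 1.
    """
    group1_mask = np.asarray(group1_mask, dtype=bool)
    if group2_mask is None:
        group2_mask = ~group1_mask
    group2_mask = np.asarray(group2_mask, dtype=bool)
    sel = group1_mask | group2_mask
    if sp.issparse(values):
        values = np.asarray(values.todense())
    V = np.asarray(values, dtype=float)[sel]
    g1 = group1_mask[sel]
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(V, axis=0)
    r1 = ranks[g1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)
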