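"""Pseudo-bulk aggregation and between-sample normalisation.

Cells are summed to sample (or sample-within-cluster) level, normalised
with trimmed-mean-of-M-values (TMM) size factors, log-CPM transformed, and
standardised per gene across samples. TMM follows the standard recipe:
reference sample chosen by upper-quartile proximity to the mean upper
quartile, 30% two-sided trimming on M-values, 5% on A-values, inverse
binomial-variance precision weights, factors rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "PseudobulkMatrix",
    "aggregate",
    "tmm_factors",
    "log_normalize",
    "zscore_genes",
    "make_pseudobulk",
]


@dataclass
class PseudobulkMatrix:
    """Sample x gene summed counts with normalised and standardised views."""

    counts: pd.DataFrame
    tmm: pd.Series
    lognorm: pd.DataFrame
    zscore: pd.DataFrame
    constant_genes: pd.Index  # genes with zero variance across samples


def aggregate(adata: AnnData, by: str = "sample", sample_key: str = "sample",
              cluster_key: str = "cluster") -> pd.DataFrame:
    """Sum counts over cells per sample or per sample-within-cluster.

    ``by`` is ``"sample"`` or ``"sample_cluster"``. Rows of the result are
    labelled by the sample (or ``sample|cluster``); the grand total equals
    the grand total of the input.
    """
    if sample_key not in adata.obs:
        raise KeyError(f"missing per-cell label {sample_key!r}")
    labels = adata.obs[sample_key].astype(str)
    if by == "sample_cluster":
        if cluster_key not in adata.obs:
            raise KeyError(f"missing per-cell label {cluster_key!r}")
        labels = labels + "|" + adata.obs[cluster_key].astype(str)
    elif by != "sample":
        raise ValueError("by must be 'sample' or 'sample_cluster'")
    cats = pd.Categorical(labels)
    ind = sp.csr_matrix(
        (np.ones(adata.n_obs), (cats.codes, np.arange(adata.n_obs))),
        shape=(len(cats.categories), adata.n_obs),
    )
    summed = np.asarray((ind @ sp.csr_matrix(adata.X)).todense())
    return pd.DataFrame(summed, index=list(cats.categories),
                        columns=adata.var_names.tolist())


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """Log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 0.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n - lo_m + 1
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n - lo_a + 1
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() == 0 or w[keep2].sum() == 0:
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM normalisation factors (geometric mean 1)."""
    mat = counts.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = mat.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("sample with all-zero counts")
    # reference: upper quartile of scaled counts closest to the mean
    with np.errstate(invalid="ignore"):
        uq = np.array([np.quantile(row[row > 0] / n, 0.75) if (row > 0).any() else 0.0
                       for row, n in zip(mat, lib)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.array([
        _tmm_pair(mat[i], mat[ref], lib[i], lib[ref]) for i in range(mat.shape[0])
    ])
    f = 2.0 ** logf
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.index, name="tmm")


def log_normalize(counts: pd.DataFrame, factors: pd.Series,
                  offset: float = 0.5) -> pd.DataFrame:
    """log2 CPM using TMM-adjusted library sizes: log2(1e6 * c / (N*f) + offset)."""
    lib = counts.sum(axis=1)
    eff = lib * factors.reindex(counts.index)
    cpm = counts.div(eff, axis=0) * 1e6
    return np.log2(cpm + offset)


def zscore_genes(lognorm: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, pd.Index]:
    """Standardise each gene across samples; constant genes become zero columns.

    Returns the z-scored matrix and the index of zero-variance (flagged)
    genes.
    """
    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0, ddof=ddof)
    constant = lognorm.columns[(sd == 0) | sd.isna()]
    sd_safe = sd.replace(0, np.nan)
    z = lognorm.sub(mu, axis=1).div(sd_safe, axis=1)
    z[constant] = 0.0
    return z, constant


def make_pseudobulk(adata: AnnData, by: str = "sample", sample_key: str = "sample",
                    cluster_key: str = "cluster", offset: float = 0.5) -> PseudobulkMatrix:
    """Aggregate, TMM-normalise, log-transform and z-score in one call."""
    counts = aggregate(adata, by=by, sample_key=sample_key, cluster_key=cluster_key)
    tmm = tmm_factors(counts)
    lognorm = log_normalize(counts, tmm, offset=offset)
    z, constant = zscore_genes(lognorm)
    return PseudobulkMatrix(counts=counts, tmm=tmm, lognorm=lognorm, zscore=z,
                            constant_genes=constant)
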