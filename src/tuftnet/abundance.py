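"""Gene expression versus rare-cluster abundance.

Two complementary directions are modelled: a univariate ordinary
least-squares fit of cluster abundance on one gene's pseudo-bulk
expression, and a genome-wide scan regressing each gene's expression on
abundance with empirical-Bayes variance moderation. Neighbourhood-level
differential abundance uses kNN neighbourhoods in PC space, a
negative-binomial GLM on per-sample neighbourhood counts with
TMM-normalised offsets, and a density-weighted ("spatial") FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import polygamma
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from tuftnet.pseudobulk import tmm_factors

__all__ = [
    "NeighbourhoodSet",
    "cluster_proportions",
    "abundance_univariate",
    "ebayes_moderate",
    "abundance_scan",
    "build_neighbourhoods",
    "da_test",
    "spatial_fdr",
    "filter_majority",
]


def cluster_proportions(labels, samples) -> pd.DataFrame:
    """Per-sample cluster fractions (rows sum to 1)."""
    df = pd.crosstab(pd.Series(samples, name="sample"),
                     pd.Series(labels, name="cluster"))
    return df.div(df.sum(axis=1), axis=0)


def abundance_univariate(abundance: pd.Series, expr: pd.Series) -> dict:
    """OLS of abundance on one gene's expression: slope and two-sided t p."""
    idx = abundance.index.intersection(expr.index)
    y = abundance[idx].to_numpy(dtype=float)
    x = expr[idx].to_numpy(dtype=float)
    n = len(idx)
    if n < 3:
        raise ValueError("need at least 3 samples")
    X = np.column_stack([np.ones(n), x])
    beta, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = resid @ resid / (n - 2)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[1, 1])
    tval = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = 2 * t_dist.sf(abs(tval), n - 2)
    return {"coefficient": float(beta[1]), "intercept": float(beta[0]),
            "t": float(tval), "p": float(p), "n": n}


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def ebayes_moderate(s2: np.ndarray, df_res: float) -> dict:
    """Empirical-Bayes shrinkage of gene-wise residual variances.

    Hyperparameters (d0, s0^2) are fitted by matching moments of log s^2
    to a scaled-F model; posterior variances are the usual weighted
    combination. d0 = inf (all variances equal) collapses every posterior
    to s0^2. A single gene falls back to no moderation with a warning.
    """
    from scipy.special import digamma

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        warnings.warn("too few genes for moderation; using raw variances")
        return {"d0": np.inf, "s0_sq": float(s2[ok].mean()) if ok.any() else 0.0,
                "s2_post": s2.copy()}
    z = np.log(s2[ok])
    e = z - digamma(df_res / 2) + np.log(df_res / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df_res / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
        s2_post = np.full_like(s2, s0_sq)
    return {"d0": float(d0), "s0_sq": float(s0_sq), "s2_post": s2_post}


def abundance_scan(lognorm: pd.DataFrame, abundance: pd.Series) -> pd.DataFrame:
    """Moderated per-gene regression of expression on cluster abundance.

    For each gene, OLS of pseudo-bulk log expression on the abundance
    covariate; residual variances are shrunk with :func:`ebayes_moderate`
    and the moderated t uses d0 + df_res degrees of freedom. The abundance
    covariate is scaled to unit variance so the reported logFC is the log2
    expression change per standard deviation of abundance -- a raw
    cluster fraction spans only a few percent, which would inflate every
    slope and make a fold-change cutoff meaningless. Columns: logFC
    (slope), t_mod, p, fdr (BH). Constant genes are dropped with a
    warning.
    """
    idx = lognorm.index.intersection(abundance.index)
    Y = lognorm.loc[idx].to_numpy(dtype=float)
    x = abundance[idx].to_numpy(dtype=float)
    if x.std(ddof=1) == 0:
        raise ValueError("abundance covariate is constant")
    x = (x - x.mean()) / x.std(ddof=1)
    n = len(idx)
    if n < 4:
        raise ValueError("need at least 4 samples for the moderated scan")
    sd = Y.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes")
    genes = lognorm.columns[keep]
    Y = Y[:, keep]
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df_res = n - 2
    s2 = (resid**2).sum(axis=0) / df_res
    mod = ebayes_moderate(s2, df_res)
    xtx_inv11 = np.linalg.inv(X.T @ X)[1, 1]
    se = np.sqrt(mod["s2_post"] * xtx_inv11)
    tmod = np.where(se > 0, beta[1] / se, 0.0)
    df_total = mod["d0"] + df_res if np.isfinite(mod["d0"]) else 1e9
    p = 2 * t_dist.sf(np.abs(tmod), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"logFC": beta[1], "t_mod": tmod, "p": p,
                        "fdr": np.maximum(fdr, p)},
                       index=pd.Index(genes, name="gene"))
    return out.sort_values("p", kind="mergesort")


@dataclass
class NeighbourhoodSet:
    index_cells: np.ndarray  # positions of index cells
    members: list  # per-neighbourhood member positions
    counts: pd.DataFrame  # neighbourhood x sample
    kth_nn_distance: np.ndarray
    majority_cluster: np.ndarray
    majority_proportion: np.ndarray


def build_neighbourhoods(scores: np.ndarray, samples, labels, k: int = 250,
                         n_pcs: int = 4, sample_fraction: float = 0.1,
                         seed: int = 0) -> NeighbourhoodSet:
    """kNN neighbourhoods around refined, sampled index cells.

    Index cells are sampled at ``sample_fraction``, replaced by the member
    closest to the neighbourhood centroid, and deduplicated. Each
    neighbourhood is the index cell's k nearest neighbours (itself
    included) in the first ``n_pcs`` components; per-sample counts, the
    kth-NN distance (for the spatial FDR) and the majority cluster
    annotation are stored.
    """
    rng = np.random.default_rng(seed)
    S = np.asarray(scores)[:, :n_pcs]
    n = S.shape[0]
    k = min(k, n - 1)
    samples = pd.Series(np.asarray(samples).astype(str))
    labels = np.asarray(labels)
    n_index = max(1, int(round(sample_fraction * n)))
    cand = rng.choice(n, size=n_index, replace=False)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(S)
    dist, idx = nn.kneighbors(S[cand])
    # refinement: move each index to the member nearest the neighbourhood centroid
    refined = []
    for row in idx:
        centroid = S[row].mean(axis=0)
        refined.append(row[np.argmin(np.linalg.norm(S[row] - centroid, axis=1))])
    refined = np.unique(refined)
    dist, idx = nn.kneighbors(S[refined])
    # distinct index cells can resolve to identical member sets; keep one
    seen: dict = {}
    for pos, row in enumerate(idx):
        seen.setdefault(frozenset(row.tolist()), pos)
    uniq = sorted(seen.values())
    refined, dist, idx = refined[uniq], dist[uniq], idx[uniq]
    sample_cats = sorted(samples.unique())
    counts = np.zeros((len(refined), len(sample_cats)), dtype=int)
    cat_pos = {c: j for j, c in enumerate(sample_cats)}
    members, maj_c, maj_p = [], [], []
    for i, row in enumerate(idx):
        members.append(row)
        for s in samples.iloc[row]:
            counts[i, cat_pos[s]] += 1
        vals, cnts = np.unique(labels[row], return_counts=True)
        j = int(np.argmax(cnts))
        maj_c.append(vals[j])
        maj_p.append(cnts[j] / len(row))
    return NeighbourhoodSet(
        index_cells=refined,
        members=members,
        counts=pd.DataFrame(counts, columns=sample_cats),
        kth_nn_distance=dist[:, -1],
        majority_cluster=np.asarray(maj_c),
        majority_proportion=np.asarray(maj_p),
    )


def _moment_dispersion(counts: np.ndarray, offsets: np.ndarray,
                       groups: np.ndarray) -> float:
    """Shared NB dispersion by moments from group-wise Poisson residuals."""
    num = den = 0.0
    for g in np.unique(groups):
        sel = groups == g
        y = counts[:, sel]
        off = offsets[sel]
        rate = y.sum(axis=1, keepdims=True) / off.sum()
        mu = rate * off[None, :]
        ok = mu > 0
        num += np.sum(((y - mu) ** 2 - mu)[ok])
        den += np.sum((mu**2)[ok])
    return max(num / den, 1e-8) if den > 0 else 1e-8


def da_test(nset: NeighbourhoodSet, sample_groups: pd.Series,
            weighted_fdr: bool = True) -> pd.DataFrame:
    """Per-neighbourhood differential abundance between sample groups.

    NB GLM of neighbourhood counts on group with a log(total cells x TMM
    factor) offset; common dispersion by moment matching across
    neighbourhoods; the likelihood-ratio statistic is referred to an
    F(1, n_samples - 2) distribution rather than chi-square(1) -- the
    finite-sample correction in the spirit of the quasi-likelihood F-test,
    without which the test is anticonservative at ~11 samples. logFC in
    log2 units; spatial FDR by kth-NN-distance-weighted BH (plain BH when
    ``weighted_fdr`` is False).
    """
    groups = sample_groups.reindex(nset.counts.columns)
    if groups.isna().any():
        raise ValueError("missing group for some samples")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two sample groups required")
    g = (groups == levels[1]).to_numpy().astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("each group needs at least two samples")
    Y = nset.counts.to_numpy(dtype=float)
    totals = Y.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("sample with zero neighbourhood counts")
    tmm = tmm_factors(nset.counts.T).reindex(nset.counts.columns).to_numpy()
    offset = np.log(totals * tmm)
    alpha = _moment_dispersion(Y, np.exp(offset), g)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    X_full = np.column_stack([np.ones(Y.shape[1]), g])
    X_null = X_full[:, :1]
    logfc = np.zeros(Y.shape[0])
    pvals = np.ones(Y.shape[0])
    for i in range(Y.shape[0]):
        y = Y[i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
                null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
                stat = max(0.0, 2 * (full.llf - null.llf))
                pvals[i] = f_dist.sf(stat, 1, Y.shape[1] - 2)
                logfc[i] = full.params[1] / np.log(2)
            except Exception:
                pvals[i] = 1.0
    sfdr = spatial_fdr(pvals, nset.kth_nn_distance) if weighted_fdr else \
        multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "logFC": logfc,
        "p": pvals,
        "spatial_fdr": sfdr,
        "majority_cluster": nset.majority_cluster,
        "majority_proportion": nset.majority_proportion,
    })


def spatial_fdr(pvals: np.ndarray, kth_nn_distance: np.ndarray) -> np.ndarray:
    """Density-weighted BH: weights are reciprocal kth-NN distances."""
    p = np.asarray(pvals, dtype=float)
    d = np.asarray(kth_nn_distance, dtype=float)
    d[d <= 0] = d[d > 0].min() if np.any(d > 0) else 1.0
    w = 1.0 / d
    order = np.argsort(p, kind="mergesort")
    cw = np.cumsum(w[order])
    adj = p[order] * w.sum() / cw
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def filter_majority(nset: NeighbourhoodSet, results: pd.DataFrame,
                    min_majority: float = 0.8, alpha: float = 0.01) -> pd.DataFrame:
    """Drop mixed neighbourhoods and flag significance.

    Keeps neighbourhoods whose majority-cluster proportion exceeds
    ``min_majority``; adds a ``significant`` flag at spatial FDR < alpha.
    """
    out = results[results["majority_proportion"] > min_majority].copy()
    out["significant"] = out["spatial_fdr"] < alpha
    return out
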