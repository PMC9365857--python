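"""Cell-type-specificity machinery around the co-expression results.

Covers four analyses: (i) splitting samples into high/low expressors of a
module's hub genes by complete-linkage clustering, with an empirical
permutation null built from random same-size gene draws; (ii) an
"auxiliary module" of target genes tied to the driver within one cluster,
and its cross-cluster preservation summarised by cor.kME and average
module membership; (iii) per-cluster variability tables of pseudo-bulk
and single-cell variance; (iv) a permutation test for the fold change of
normalised single-cell variance between two cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from anndata import AnnData
from scipy.spatial.distance import pdist

from tuftnet.cluster import standardized_variance
from tuftnet.coexpr import GeneModuleStats, corr_pvalues, module_eigengenes
from tuftnet.pseudobulk import log_normalize, tmm_factors, zscore_genes

__all__ = [
    "SampleGrouping",
    "PreservationResult",
    "empirical_p",
    "group_samples_by_hub_genes",
    "grouping_permutation_p",
    "define_auxiliary_module",
    "preservation_cor_kme",
    "pairwise_correlation_panel",
    "percluster_variability",
    "variance_foldchange_test",
]


@dataclass
class SampleGrouping:
    partition: pd.Series  # sample -> "high" / "low"
    empirical_p: float
    n_perm: int
    n_matches: int

    def __post_init__(self) -> None:
        groups = set(self.partition)
        if groups != {"high", "low"}:
            raise ValueError("partition must contain both 'high' and 'low'")
        if abs(self.empirical_p - self.n_matches / self.n_perm) > 1e-12:
            raise ValueError("empirical_p must equal n_matches / n_perm")


@dataclass
class PreservationResult:
    table: pd.DataFrame  # per cluster: cor_kme, p, average_mm, n_genes
    kme: pd.DataFrame  # aux gene x cluster kME values


def empirical_p(n_matches: int, n_perm: int) -> float:
    """Empirical p-value under the count/total convention (no smoothing)."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not 0 <= n_matches <= n_perm:
        raise ValueError("n_matches must lie in [0, n_perm]")
    return n_matches / n_perm


def _root_bipartition(values: np.ndarray, sample_names) -> pd.Series:
    """Two branches at the root of a complete-linkage tree on Euclidean rows."""
    d = pdist(values)
    if np.all(d == 0):
        raise ValueError("degenerate dendrogram: all samples identical")
    Z = sch.linkage(d, method="complete")
    labels = sch.fcluster(Z, t=2, criterion="maxclust")
    return pd.Series(labels, index=sample_names)


def group_samples_by_hub_genes(zscore_pb: pd.DataFrame, hub_genes) -> pd.Series:
    """Root split of samples clustered on hub-gene z-scores.

    The branch with the lower mean hub-gene expression is labelled "low".
    """
    hub_genes = [g for g in hub_genes if g in zscore_pb.columns]
    if not hub_genes:
        raise ValueError("no hub genes present in the expression matrix")
    sub = zscore_pb[hub_genes]
    raw = _root_bipartition(sub.to_numpy(), zscore_pb.index)
    means = sub.mean(axis=1).groupby(raw).mean()
    low = means.idxmin()
    return raw.map(lambda v: "low" if v == low else "high")


def _partition_key(labels: pd.Series) -> frozenset:
    groups: dict = {}
    for s, g in labels.items():
        groups.setdefault(g, set()).add(s)
    return frozenset(frozenset(v) for v in groups.values())


def grouping_permutation_p(zscore_pb: pd.DataFrame, observed: pd.Series,
                           n_genes: int = 10, n_perm: int = 10000,
                           seed: int = 0) -> SampleGrouping:
    """How often random gene draws reproduce the observed sample bipartition.

    Each permutation draws ``n_genes`` genes without replacement, reclusters
    the samples (complete linkage, root cut) and counts a match when the
    unordered bipartition equals the observed one. The empirical p-value is
    matches / permutations.
    """
    if n_genes > zscore_pb.shape[1]:
        raise ValueError("n_genes exceeds the number of genes")
    rng = np.random.default_rng(seed)
    target = _partition_key(observed)
    X = zscore_pb.to_numpy()
    names = zscore_pb.index
    matches = 0
    for _ in range(n_perm):
        cols = rng.choice(X.shape[1], size=n_genes, replace=False)
        try:
            part = _root_bipartition(X[:, cols], names)
        except ValueError:
            continue
        if _partition_key(part) == target:
            matches += 1
    part_named = observed.map(str)
    if set(part_named) != {"high", "low"}:
        # observed may come directly from _root_bipartition; relabel by mean
        part_named = observed.map(
            lambda v: "low" if v == observed.iloc[0] else "high")
    return SampleGrouping(partition=part_named, empirical_p=empirical_p(matches, n_perm),
                          n_perm=n_perm, n_matches=matches)


def define_auxiliary_module(stats: GeneModuleStats, target_genes, module: str,
                            gs_min: float = 0.5, gs_p_max: float = 0.05,
                            mm_min: float = 0.5) -> list[str]:
    """Target genes of one module tied to the driver trait.

    Keeps targets with gene significance above ``gs_min`` (nominally
    significant at ``gs_p_max``) and module membership above ``mm_min``.
    """
    t = stats.table
    sel = t.index.isin(set(target_genes)) & (t["module"] == module) \
        & (t["GS"] > gs_min) & (t["GS_p"] < gs_p_max) & (t["MM"] > mm_min)
    return t.index[sel].tolist()


def _kme_vector(pb_z: pd.DataFrame, aux_genes: list[str]) -> pd.Series | None:
    """kME of each auxiliary gene against the auxiliary-module eigengene."""
    present = [g for g in aux_genes
               if g in pb_z.columns and pb_z[g].std(ddof=1) > 0]
    if len(present) < 2:
        return None
    modules = pd.Series("aux", index=present)
    eig = module_eigengenes(pb_z[present], modules)["aux"].to_numpy()
    out = pd.Series(0.0, index=aux_genes)
    for g in present:
        out[g] = np.corrcoef(pb_z[g].to_numpy(), eig)[0, 1]
    out[[g for g in aux_genes if g not in present]] = np.nan
    return out


def preservation_cor_kme(percluster_pb_z: dict, ref_cluster,
                         aux_genes: list[str]) -> PreservationResult:
    """Cross-cluster preservation of the auxiliary module.

    ``percluster_pb_z`` maps cluster id -> sample x gene z-scored
    pseudo-bulk. For each cluster the auxiliary genes' kME vector (against
    the auxiliary eigengene computed within that cluster) is correlated
    with the reference cluster's vector; the p-value is the two-sided
    Student t of that correlation. Clusters with fewer than two auxiliary
    genes with usable variance are excluded. The reference's own cor.kME
    is 1 by construction.
    """
    ref_kme = _kme_vector(percluster_pb_z[ref_cluster], aux_genes)
    if ref_kme is None:
        raise ValueError("reference cluster lacks usable auxiliary genes")
    rows, kme_cols = [], {}
    for cid, pb in percluster_pb_z.items():
        kme = _kme_vector(pb, aux_genes)
        if kme is None:
            continue
        kme_cols[cid] = kme
        both = (~kme.isna()) & (~ref_kme.isna())
        m = int(both.sum())
        if m < 3:
            continue
        if cid == ref_cluster:
            r = 1.0
        else:
            a, b = kme[both].to_numpy(), ref_kme[both].to_numpy()
            r = float(np.corrcoef(a, b)[0, 1]) if (a.std() > 0 and b.std() > 0) else 0.0
        rows.append({
            "cluster": cid,
            "cor_kme": r,
            "p": float(corr_pvalues(np.array([r]), m)[0]),
            "average_mm": float(kme[both].mean()),
            "n_genes": m,
        })
    table = pd.DataFrame(rows).set_index("cluster")
    return PreservationResult(table=table, kme=pd.DataFrame(kme_cols))


def pairwise_correlation_panel(percluster_pb: dict, genes: list[str],
                               alpha: float = 0.05) -> dict:
    """Per-cluster pairwise Pearson correlations with non-significant entries masked.

    Returns cluster -> {"cor", "mask", "any_significant"}; the mask is True
    where p < alpha (diagonal excluded).
    """
    out = {}
    for cid, pb in percluster_pb.items():
        present = [g for g in genes if g in pb.columns and pb[g].std(ddof=1) > 0]
        sub = pb[present]
        n = sub.shape[0]
        cor = pd.DataFrame(np.corrcoef(sub.to_numpy().T),
                           index=present, columns=present)
        p = pd.DataFrame(corr_pvalues(cor.to_numpy(), n),
                         index=present, columns=present)
        mask = p < alpha
        np.fill_diagonal(mask.to_numpy(), False)
        out[cid] = {"cor": cor, "mask": mask,
                    "any_significant": bool(mask.to_numpy().any())}
    return out


def percluster_variability(adata: AnnData, labels, genes=None,
                           sample_key: str = "sample") -> pd.DataFrame:
    """Per gene x cluster variability: pseudo-bulk z-score variance, raw and
    vst-standardised single-cell variance, plus the argmax cluster per gene.

    Returns a tidy frame indexed by (gene, cluster) with a companion
    ``argmax`` attribute per measure available via groupby.
    """
    import scipy.sparse as sp

    labels = np.asarray(labels)
    if genes is None:
        genes = adata.var_names.tolist()
    gidx = [adata.var_names.get_loc(g) for g in genes]

    # pseudo-bulk per sample-within-cluster, normalised and z-scored jointly
    # across all units so per-cluster variances are comparable
    units = pd.Series(adata.obs[sample_key].astype(str).to_numpy()
                      + "|" + labels.astype(str))
    X = sp.csr_matrix(adata.X)[:, gidx]
    unit_counts = pd.DataFrame(np.asarray(X.todense()),
                               index=units.to_numpy(),
                               columns=genes).groupby(level=0).sum()
    unit_counts = unit_counts[unit_counts.sum(axis=1) > 0]
    pb_z = None
    if unit_counts.shape[0] >= 2:
        try:
            f = tmm_factors(unit_counts)
            pb_z, _ = zscore_genes(log_normalize(unit_counts, f))
        except ValueError:
            pb_z = None

    rows = []
    for cid in np.unique(labels):
        sub = adata[labels == cid]
        dense = np.asarray(sp.csr_matrix(sub.X)[:, gidx].todense())
        raw_var = dense.var(axis=0, ddof=1) if dense.shape[0] > 1 else np.zeros(len(genes))
        std_var = standardized_variance(dense) if dense.shape[0] > 2 else np.zeros(len(genes))
        pb_var = np.zeros(len(genes))
        if pb_z is not None:
            in_cluster = pb_z.index.str.endswith(f"|{cid}")
            if in_cluster.sum() >= 2:
                pb_var = pb_z.loc[in_cluster].var(axis=0, ddof=1).to_numpy()
        for j, g in enumerate(genes):
            rows.append({"gene": g, "cluster": cid, "pb_z_var": pb_var[j],
                         "sc_raw_var": raw_var[j], "sc_std_var": std_var[j]})
    return pd.DataFrame(rows).set_index(["gene", "cluster"])


def variability_argmax(table: pd.DataFrame, measure: str = "pb_z_var") -> pd.Series:
    """Cluster maximising the given variability measure, per gene."""
    return table[measure].groupby(level="gene").idxmax().map(lambda t: t[1])


def variance_foldchange_test(norm_var_a: pd.Series, norm_var_b: pd.Series,
                             target_genes, n_perm: int = 100000,
                             n_boot: int = 10000, seed: int = 0) -> dict:
    """Permutation test of variance fold change A/B for a target gene set.

    The null draws same-size random gene sets from the shared expressed
    universe and records the mean fold change; p is +1-smoothed. The 95% CI
    of the mean fold change is a percentile bootstrap over target genes.
    """
    rng = np.random.default_rng(seed)
    shared = norm_var_a.index.intersection(norm_var_b.index)
    shared = shared[(norm_var_a[shared] > 0) & (norm_var_b[shared] > 0)]
    fc_all = (norm_var_a[shared] / norm_var_b[shared]).astype(float)
    targets = [g for g in target_genes if g in fc_all.index]
    dropped = [g for g in target_genes if g not in fc_all.index]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} target genes with zero/missing variance")
    if not targets:
        raise ValueError("no target genes in the shared expressed universe")
    fc = fc_all[targets]
    obs_mean = float(fc.mean())
    m = len(targets)
    vals = fc_all.to_numpy()
    null_means = np.empty(n_perm)
    for b in range(n_perm):
        null_means[b] = vals[rng.choice(vals.size, size=m, replace=False)].mean()
    p = (1.0 + np.sum(null_means >= obs_mean)) / (1.0 + n_perm)
    boot_idx = rng.integers(0, m, size=(n_boot, m))
    boot_means = fc.to_numpy()[boot_idx].mean(axis=1)
    ci = np.quantile(boot_means, [0.025, 0.975])
    return {
        "fold_changes": fc,
        "median": float(fc.median()),
        "mean": obs_mean,
        "range": (float(fc.min()), float(fc.max())),
        "ci95": (float(ci[0]), float(ci[1])),
        "p": float(p),
        "n_perm": n_perm,
    }
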