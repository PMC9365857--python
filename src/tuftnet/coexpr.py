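"""Signed weighted gene co-expression networks on pseudo-bulk expression.

Implements the classic weighted-network toolkit: soft-threshold selection
by scale-free topology fit, signed adjacency a_ij = ((1 + cor_ij)/2)^beta,
topological overlap (TOM), module detection by dynamic cutting of the
average-linkage tree on 1 - TOM, module eigengenes, module--trait
correlation statistics, per-gene module membership / gene significance /
intramodular connectivity, and hub-gene selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoexprNetwork",
    "GeneModuleStats",
    "pick_soft_threshold",
    "adjacency_signed",
    "tom_matrix",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlations",
    "gene_statistics",
    "hub_genes",
    "build_network",
    "export_edges",
    "corr_pvalues",
]

# WGCNA-style colour palette; modules are named by decreasing size.
_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
UNASSIGNED = "grey"


@dataclass
class CoexprNetwork:
    cor: pd.DataFrame
    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    linkage: np.ndarray
    modules: pd.Series  # gene -> colour label, "grey" unassigned
    eigengenes: pd.DataFrame  # sample x module
    power_table: pd.DataFrame = field(default=None)


def corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided Student-t p-values for Pearson correlations with n samples."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-15, 1 - 1e-15)
    df = n - 2
    tstat = r * np.sqrt(df) / np.sqrt(1 - r**2)
    return 2 * t_dist.sf(np.abs(tstat), df)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of log10(freq) on log10(mean k) over connectivity bins."""
    k = k[np.isfinite(k)]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, float(np.mean(k)) if k.size else 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 0 and k[m].mean() > 0:
            xs.append(np.log10(k[m].mean()))
            ys.append(np.log10(m.sum() / k.size))
    if len(xs) < 3:
        return 0.0, float(k.mean())
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = np.sum((ys - pred) ** 2)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(k.mean())


def pick_soft_threshold(zscore_expr: pd.DataFrame, powers=range(1, 21),
                        rsq_cut: float = 0.85) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``rsq_cut``.

    Falls back to the power maximising the signed fit when no candidate
    reaches the cut. Also returns the per-power fit/connectivity table.
    """
    powers = list(powers)
    cor = np.corrcoef(zscore_expr.to_numpy().T)
    rows = []
    for beta in powers:
        adj = ((1 + cor) / 2.0) ** beta
        k = adj.sum(axis=1) - 1.0
        sft, mean_k = _scale_free_fit(k)
        rows.append({"power": beta, "sft_r2": sft, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    ok = table[table["sft_r2"] >= rsq_cut]
    beta = int(ok["power"].iloc[0]) if len(ok) else int(
        table.loc[table["sft_r2"].idxmax(), "power"])
    return beta, table


def adjacency_signed(cor: np.ndarray | pd.DataFrame, beta: int):
    """Signed adjacency a_ij = ((1 + cor_ij)/2)^beta."""
    return ((1 + cor) / 2.0) ** beta


def tom_matrix(adjacency: np.ndarray | pd.DataFrame):
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)+1-a_ij).

    l_ij sums a_iu * a_uj over u distinct from i and j; k is connectivity
    excluding the self-edge. The diagonal is set to 1.
    """
    names = adjacency.index if isinstance(adjacency, pd.DataFrame) else None
    A = np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=1) - np.diag(A)
    L = A @ A - A * (np.diag(A)[:, None] + np.diag(A)[None, :])
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if names is not None:
        return pd.DataFrame(tom, index=names, columns=names)
    return tom


def module_eigengenes(zscore_expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """First singular direction of each module, unit norm over samples.

    Each eigengene is sign-oriented to correlate positively with the
    module's average standardised expression.
    """
    cols = {}
    for label in [m for m in modules.unique() if m != UNASSIGNED]:
        genes = modules.index[modules == label]
        sub = zscore_expr[genes].to_numpy()
        sd = sub.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        sub = (sub - sub.mean(axis=0)) / sd
        u, s, _ = np.linalg.svd(sub, full_matrices=False)
        e = u[:, 0]
        avg = sub.mean(axis=1)
        if np.dot(e, avg) < 0:
            e = -e
        cols[label] = e
    return pd.DataFrame(cols, index=zscore_expr.index)


def _first_pc(X: np.ndarray) -> np.ndarray:
    """First left singular vector of a column-standardised matrix."""
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    u, _, _ = np.linalg.svd(Xs, full_matrices=False)
    e = u[:, 0]
    if np.dot(e, Xs.mean(axis=1)) < 0:
        e = -e
    return e


def _branch_dissimilarity(X: np.ndarray, idx_a, idx_b) -> float:
    """1 - cor between the eigengenes of two leaf sets (column indices)."""
    ea = _first_pc(X[:, idx_a]) if len(idx_a) > 1 else X[:, idx_a[0]]
    eb = _first_pc(X[:, idx_b]) if len(idx_b) > 1 else X[:, idx_b[0]]
    if np.std(ea) == 0 or np.std(eb) == 0:
        return 1.0
    return float(1 - np.corrcoef(ea, eb)[0, 1])


def detect_modules(tom: pd.DataFrame, zscore_expr: pd.DataFrame,
                   min_module_size: int = 30, merge_height: float = 0.25
                   ) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Modules by dynamic cutting of the average-linkage tree on 1 - TOM.

    The tree is cut recursively from the root: at each internal node the
    eigengenes of the two child branches are compared, and the node is
    split whenever their dissimilarity (1 - correlation) reaches
    ``merge_height``; a node whose children are closer than that becomes a
    single module. Children smaller than ``min_module_size`` that fall off
    a split are unassigned ("grey") -- this strips the chained noise genes
    that average linkage attaches to coherent branches one at a time.
    Finally, modules whose eigengene dissimilarity falls below
    ``merge_height`` are merged; labels are palette colours ordered by
    decreasing module size.
    """
    genes = list(tom.index)
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    n = len(genes)
    labels = pd.Series(UNASSIGNED, index=genes)
    if min_module_size > n:
        return labels, pd.DataFrame(index=zscore_expr.index), Z

    X = zscore_expr[genes].to_numpy()
    tree = sch.to_tree(Z)

    def leaves(node):
        return node.pre_order(lambda x: x.id)

    def split(node) -> list[list[int]]:
        if node.count < min_module_size:
            return []
        if node.is_leaf():
            return []
        lv_l, lv_r = leaves(node.left), leaves(node.right)
        if _branch_dissimilarity(X, lv_l, lv_r) < merge_height:
            return [lv_l + lv_r]
        return split(node.left) + split(node.right)

    groups = split(tree)
    groups.sort(key=len, reverse=True)
    for i, g in enumerate(groups):
        name = _PALETTE[i] if i < len(_PALETTE) else f"module{i + 1}"
        labels.iloc[g] = name

    labels = _refine_by_kme(labels, X, genes, min_module_size)
    labels = _merge_close_modules(labels, zscore_expr, merge_height)
    eig = module_eigengenes(zscore_expr, labels)
    return labels, eig, Z


def _refine_by_kme(labels: pd.Series, X: np.ndarray, genes: list,
                   min_module_size: int) -> pd.Series:
    """Strip module members whose kME is a robust outlier (median - 3 MAD).

    Average linkage chains loose genes onto coherent branches one at a
    time; at the gene level these stragglers show a clearly lower
    correlation with the module eigengene than the core. Modules whose kME
    spread is degenerate (MAD 0) are left untouched, as are modules that
    would fall below ``min_module_size``.
    """
    labels = labels.copy()
    pos = {g: i for i, g in enumerate(genes)}
    for mod in [m for m in labels.unique() if m != UNASSIGNED]:
        members = labels.index[labels == mod].tolist()
        idx = [pos[g] for g in members]
        e = _first_pc(X[:, idx])
        kme = np.array([
            np.corrcoef(X[:, i], e)[0, 1] if np.std(X[:, i]) > 0 else 0.0
            for i in idx
        ])
        med = np.median(kme)
        mad = np.median(np.abs(kme - med))
        if mad == 0:
            continue
        keep = kme >= med - 3 * mad
        if keep.sum() < min_module_size:
            continue
        for g, k in zip(members, keep):
            if not k:
                labels[g] = UNASSIGNED
    return labels


def _merge_close_modules(labels: pd.Series, zscore_expr: pd.DataFrame,
                         merge_height: float) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != UNASSIGNED]
        if len(mods) < 2:
            break
        eig = module_eigengenes(zscore_expr, labels)
        diss = 1 - np.corrcoef(eig[mods].to_numpy().T)
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        keep, drop = sorted([mods[i], mods[j]],
                            key=lambda m: -(labels == m).sum())
        labels[labels == drop] = keep
    # relabel by size with palette order
    mods = [m for m in labels.unique() if m != UNASSIGNED]
    mods.sort(key=lambda m: -(labels == m).sum())
    remap = {m: (_PALETTE[i] if i < len(_PALETTE) else f"module{i + 1}")
             for i, m in enumerate(mods)}
    return labels.map(lambda m: remap.get(m, UNASSIGNED))


def module_trait_correlations(eigengenes: pd.DataFrame,
                              traits: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pearson module--trait correlations with t p-values and BH FDR.

    Multi-level categorical traits should be one-hot binarised beforehand.
    BH is applied across the full module x trait grid.
    """
    if eigengenes.shape[1] == 0 or traits.shape[1] == 0:
        raise ValueError("need at least one module eigengene and one trait")
    n = eigengenes.shape[0]
    cor = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    for m in eigengenes.columns:
        for tr in traits.columns:
            x, y = eigengenes[m].to_numpy(), traits[tr].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                cor.loc[m, tr] = 0.0
            else:
                cor.loc[m, tr] = np.corrcoef(x, y)[0, 1]
    p = pd.DataFrame(corr_pvalues(cor.to_numpy(), n), index=cor.index,
                     columns=cor.columns)
    flat = p.to_numpy().ravel()
    fdr = multipletests(flat, method="fdr_bh")[1].reshape(p.shape)
    fdr = pd.DataFrame(np.maximum(fdr, p.to_numpy()), index=p.index, columns=p.columns)
    return {"cor": cor, "p": p, "fdr": fdr}


@dataclass
class GeneModuleStats:
    table: pd.DataFrame  # per gene: module, MM, MM_p, GS, GS_p, kIM, max_adj


def gene_statistics(zscore_expr: pd.DataFrame, eigengenes: pd.DataFrame,
                    modules: pd.Series, trait: pd.Series,
                    adjacency: pd.DataFrame) -> GeneModuleStats:
    """Per-gene MM (kME), GS, scaled intramodular connectivity and max adjacency.

    MM is the correlation with the gene's own module eigengene (0 for grey
    genes), GS the correlation with the trait, kIM the within-module
    adjacency sum scaled by the module maximum (singletons score 0).
    """
    n = zscore_expr.shape[0]
    genes = list(zscore_expr.columns)
    tvals = trait.reindex(zscore_expr.index).to_numpy(dtype=float)
    mm = np.zeros(len(genes))
    gs = np.zeros(len(genes))
    kim_raw = np.zeros(len(genes))
    max_adj = np.zeros(len(genes))
    X = zscore_expr.to_numpy()
    for i, g in enumerate(genes):
        x = X[:, i]
        if np.std(x) > 0 and np.std(tvals) > 0:
            gs[i] = np.corrcoef(x, tvals)[0, 1]
        mod = modules.get(g, UNASSIGNED)
        if mod != UNASSIGNED and mod in eigengenes:
            e = eigengenes[mod].to_numpy()
            if np.std(x) > 0:
                mm[i] = np.corrcoef(x, e)[0, 1]
    A = adjacency.to_numpy()
    for mod in [m for m in modules.unique() if m != UNASSIGNED]:
        idx = [genes.index(g) for g in modules.index[modules == mod] if g in genes]
        if len(idx) < 2:
            continue
        sub = A[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        sums = sub.sum(axis=1)
        mx = sums.max()
        for j, gi in enumerate(idx):
            kim_raw[gi] = sums[j] / mx if mx > 0 else 0.0
            max_adj[gi] = sub[j].max()
    table = pd.DataFrame(
        {
            "module": [modules.get(g, UNASSIGNED) for g in genes],
            "MM": mm,
            "MM_p": corr_pvalues(mm, n),
            "GS": gs,
            "GS_p": corr_pvalues(gs, n),
            "kIM": kim_raw,
            "max_adj": max_adj,
        },
        index=pd.Index(genes, name="gene"),
    )
    return GeneModuleStats(table=table)


def hub_genes(stats: GeneModuleStats, module: str, mm_min: float = 0.7,
              kim_min: float = 0.7, adj_min: float = 0.3) -> list[str]:
    """Module genes with MM, scaled kIM and max intramodular adjacency above cuts."""
    t = stats.table
    sel = (t["module"] == module) & (t["MM"] > mm_min) & (t["kIM"] > kim_min) \
        & (t["max_adj"] > adj_min)
    return t.index[sel].tolist()


def export_edges(adjacency: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Edge list (gene1, gene2, adjacency) above a threshold, for plotting."""
    A = adjacency.to_numpy()
    iu = np.triu_indices_from(A, k=1)
    keep = A[iu] > threshold
    return pd.DataFrame({
        "gene1": adjacency.index.to_numpy()[iu[0][keep]],
        "gene2": adjacency.columns.to_numpy()[iu[1][keep]],
        "adjacency": A[iu][keep],
    })


def build_network(zscore_expr: pd.DataFrame, beta: int | None = None,
                  min_module_size: int = 30, merge_height: float = 0.25,
                  powers=range(1, 21)) -> CoexprNetwork:
    """Full pipeline: correlation -> soft power -> adjacency -> TOM -> modules."""
    sd = zscore_expr.std(axis=0, ddof=1)
    zscore_expr = zscore_expr.loc[:, sd > 0]
    genes = zscore_expr.columns
    cor = pd.DataFrame(np.corrcoef(zscore_expr.to_numpy().T),
                       index=genes, columns=genes)
    table = None
    if beta is None:
        beta, table = pick_soft_threshold(zscore_expr, powers=powers)
    adj = adjacency_signed(cor, beta)
    tom = tom_matrix(adj)
    modules, eig, Z = detect_modules(tom, zscore_expr,
                                     min_module_size=min_module_size,
                                     merge_height=merge_height)
    return CoexprNetwork(cor=cor, beta=beta, adjacency=adj, tom=tom, linkage=Z,
                         modules=modules, eigengenes=eig, power_table=table)
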