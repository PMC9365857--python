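"""Synthetic multi-sample scRNA-seq cohorts with planted ground truth.

The generator emulates the structure of a small single-cell cohort in which
a latent per-sample "driver activity" (a stand-in for genotype-driven
cis-gene expression) simultaneously (i) scales the mean expression of a
planted target-gene module expressed predominantly in one rare cluster and
(ii) shifts that cluster's per-sample abundance on the log-odds scale.
Counts are negative-binomial with per-cell lognormal library-size scaling.

Every downstream stage of the package can therefore be validated against
the planted truth: module membership, rare-cluster cell identity, and the
driver--abundance coupling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData
from scipy.special import expit, logit

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "write_fixture", "read_fixture"]


def _default_module(n: int = 60) -> list[str]:
    return [f"MOD{i + 1:03d}" for i in range(n)]


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults describe the reference study conditions: 11 samples of roughly
    450 cells each, 1,500 genes, 12 transcriptional clusters of which one
    ("the rare cluster") holds ~1.5% of cells, a 60-gene planted module
    whose rare-cluster mean scales 4-fold per unit driver activity, and a
    unit log-odds abundance coupling.
    """

    n_samples: int = 11
    n_genes: int = 1500
    n_clusters: int = 12
    rare_cluster_index: int = 11
    base_abundance: np.ndarray | None = None  # per-cluster fractions, sum 1
    cells_per_sample: int = 455
    cells_dispersion: float = 0.05  # NB dispersion of per-sample cell counts
    driver_gene: str = "DRIVER"
    target_module: list[str] = field(default_factory=_default_module)
    module_effect: float = 4.0  # fold on rare-cluster module means per unit activity
    abundance_coupling: float = 1.0  # slope of rare-cluster log-odds on activity
    nb_dispersion: float = 0.3
    libsize_sigma: float = 0.25
    seed: int = 0
    # baseline expression shape (counts per cell before library scaling)
    baseline_log_mean: float = np.log(0.1)
    baseline_log_sd: float = 1.0
    markers_per_cluster: int = 30
    marker_fold: float = 6.0
    module_mean_rare: float = 3.0
    module_mean_other: float = 0.02
    driver_mean: float = 1.0
    rare_fraction: float = 0.015

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_clusters, self.cells_per_sample) <= 0:
            raise ValueError("all dimensions must be positive")
        if not 0 <= self.rare_cluster_index < self.n_clusters:
            raise ValueError("rare_cluster_index out of range")
        if self.base_abundance is None:
            rest = (1.0 - self.rare_fraction) / (self.n_clusters - 1)
            ab = np.full(self.n_clusters, rest)
            ab[self.rare_cluster_index] = self.rare_fraction
            self.base_abundance = ab
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        if self.base_abundance.shape != (self.n_clusters,):
            raise ValueError("base_abundance must have one entry per cluster")
        if np.any(self.base_abundance <= 0) or np.any(self.base_abundance >= 1):
            raise ValueError("base_abundance entries must lie in (0, 1)")
        if abs(self.base_abundance.sum() - 1.0) > 1e-9:
            raise ValueError("base_abundance must sum to 1")
        if self.base_abundance[self.rare_cluster_index] > 0.05:
            raise ValueError("rare cluster base abundance must be <= 0.05")
        if self.driver_gene in self.target_module:
            raise ValueError("target_module must not contain the driver gene")
        if len(self.target_module) + 1 > self.n_genes:
            raise ValueError("target_module plus driver exceed n_genes")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "base_abundance" in payload and payload["base_abundance"] is not None:
            payload["base_abundance"] = np.asarray(payload["base_abundance"], float)
        return cls(**payload)


@dataclass
class SimTruth:
    """Planted ground truth accompanying a synthetic cohort."""

    cell_cluster: np.ndarray  # per-cell true cluster id
    sample_driver_activity: pd.Series  # latent activity per sample
    module_members: list[str]
    per_sample_rare_abundance: pd.Series  # realised rare-cluster fraction

    def __post_init__(self) -> None:
        ab = self.per_sample_rare_abundance.to_numpy()
        if np.any(ab < 0) or np.any(ab > 1):
            raise ValueError("per_sample_rare_abundance must lie in [0, 1]")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with mean mu and variance mu + dispersion * mu^2 (gamma-Poisson)."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _gene_names(config: SimConfig) -> list[str]:
    n_bg = config.n_genes - len(config.target_module) - 1
    if n_bg < 0:
        raise ValueError("n_genes too small for target module and driver")
    return [config.driver_gene] + list(config.target_module) + [
        f"BG{i + 1:04d}" for i in range(n_bg)
    ]


def generate_cohort(config: SimConfig) -> tuple[AnnData, SimTruth]:
    """Draw a full synthetic cohort.

    Returns an :class:`~anndata.AnnData` of UMI counts (cells x genes, CSR)
    with per-cell ``sample`` and ``true_cluster`` annotations, and the
    :class:`SimTruth` describing the planted structure. Identical config
    (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    S, G, K = config.n_samples, config.n_genes, config.n_clusters
    genes = _gene_names(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    module_idx = np.array([gene_index[g] for g in config.target_module])
    driver_idx = gene_index[config.driver_gene]

    activity = rng.normal(size=S)
    samples = [f"S{i + 1:02d}" for i in range(S)]

    # cluster-by-gene mean expression (counts per cell at unit library scale)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=G)
    means = np.tile(baseline, (K, 1))
    # module genes: near-silent outside the rare cluster, high within it
    means[:, module_idx] = config.module_mean_other
    means[config.rare_cluster_index, module_idx] = config.module_mean_rare
    means[:, driver_idx] = config.driver_mean
    # disjoint per-cluster marker sets drawn from background genes
    bg_pool = np.setdiff1d(np.arange(G), np.concatenate([module_idx, [driver_idx]]))
    bg_pool = rng.permutation(bg_pool)
    need = K * config.markers_per_cluster
    if need > bg_pool.size:
        raise ValueError("not enough background genes for per-cluster markers")
    for k in range(K):
        mk = bg_pool[k * config.markers_per_cluster : (k + 1) * config.markers_per_cluster]
        means[k, mk] *= config.marker_fold

    # per-sample abundance: shift rare log-odds, renormalise the rest
    p0 = config.base_abundance[config.rare_cluster_index]
    p_rare = expit(logit(p0) + config.abundance_coupling * activity)
    others = np.delete(config.base_abundance, config.rare_cluster_index)
    others = others / others.sum()

    blocks = []
    cell_sample: list[str] = []
    cell_cluster_parts = []
    realised = np.zeros(S)
    for s in range(S):
        n_cells = int(_nb_counts(rng, np.array([float(config.cells_per_sample)]),
                                 config.cells_dispersion)[0])
        n_cells = max(n_cells, 1)
        probs = np.insert(others * (1 - p_rare[s]), config.rare_cluster_index, p_rare[s])
        clust = rng.choice(K, size=n_cells, p=probs)
        realised[s] = np.mean(clust == config.rare_cluster_index)
        mu = means[clust, :].copy()
        mu[:, driver_idx] *= np.exp(activity[s])
        in_rare = clust == config.rare_cluster_index
        if in_rare.any():
            mu[np.ix_(in_rare, module_idx)] *= config.module_effect ** activity[s]
        libs = rng.lognormal(0.0, config.libsize_sigma, size=n_cells)
        mu *= libs[:, None]
        counts = _nb_counts(rng, mu, config.nb_dispersion)
        blocks.append(sp.csr_matrix(counts))
        cell_sample.extend([samples[s]] * n_cells)
        cell_cluster_parts.append(clust)

    X = sp.vstack(blocks).tocsr()
    cell_cluster = np.concatenate(cell_cluster_parts)
    n_total = X.shape[0]
    obs = pd.DataFrame(
        {
            "sample": pd.Categorical(cell_sample, categories=samples),
            "true_cluster": cell_cluster,
        },
        index=[f"CELL{i + 1:06d}" for i in range(n_total)],
    )
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    truth = SimTruth(
        cell_cluster=cell_cluster,
        sample_driver_activity=pd.Series(activity, index=samples, name="driver_activity"),
        module_members=list(config.target_module),
        per_sample_rare_abundance=pd.Series(realised, index=samples, name="rare_abundance"),
    )
    return adata, truth


def write_fixture(adata: AnnData, truth: SimTruth | None, outdir: str | Path) -> None:
    """Write a cohort as a CellRanger-style Matrix Market triplet plus TSVs.

    Emits ``matrix.mtx`` (genes x cells, integer), ``features.tsv``,
    ``barcodes.tsv``, ``cell_metadata.tsv`` and, when truth is given,
    ``truth_samples.tsv`` / ``truth_genes.tsv``. The triplet round-trips
    losslessly through :func:`read_fixture`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.csr_matrix(adata.X).T.tocoo()  # genes x cells, CellRanger orientation
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t", index_label="barcode")
    if truth is not None:
        pd.DataFrame(
            {
                "driver_activity": truth.sample_driver_activity,
                "rare_abundance": truth.per_sample_rare_abundance,
            }
        ).to_csv(outdir / "truth_samples.tsv", sep="\t", index_label="sample")
        pd.Series(truth.module_members, name="gene").to_csv(
            outdir / "truth_genes.tsv", sep="\t", index=False
        )


def read_fixture(indir: str | Path) -> tuple[AnnData, SimTruth | None]:
    """Read a cohort written by :func:`write_fixture` (or any MTX triplet)."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx"))
    X = sp.csr_matrix(mat).T.tocsr()
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col="barcode")
        obs.index = obs.index.astype(str)
        obs = obs.loc[barcodes]
    else:
        obs = pd.DataFrame(index=barcodes)
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.tolist()))
    truth = None
    ts_path = indir / "truth_samples.tsv"
    if ts_path.exists():
        ts = pd.read_csv(ts_path, sep="\t", index_col="sample")
        tg = pd.read_csv(indir / "truth_genes.tsv", sep="\t")["gene"].astype(str).tolist()
        cc = (obs["true_cluster"].to_numpy() if "true_cluster" in obs
              else np.full(adata.n_obs, -1))
        truth = SimTruth(
            cell_cluster=cc,
            sample_driver_activity=ts["driver_activity"],
            module_members=tg,
            per_sample_rare_abundance=ts["rare_abundance"],
        )
    if adata.n_obs and adata.X.size and int(adata.X.min()) < 0:
        warnings.warn("negative entries in count matrix")
    return adata, truth
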