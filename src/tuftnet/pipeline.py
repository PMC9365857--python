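"""End-to-end orchestration: counts in, specificity report out.

Stages: (simulate) -> QC -> pseudo-bulk -> pan co-expression network ->
clustering -> markers -> enrichment -> hub-gene sample grouping ->
per-cluster pseudo-bulk -> intra-cluster network -> auxiliary-module
preservation -> variability -> abundance scan -> neighbourhood
differential abundance. A single seed fans out to per-stage generators
(stage-name hashed) so toggling one stage does not shift another's
randomness. All stage defaults are the reference analysis values.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tuftnet import abundance as ab
from tuftnet import cluster as cl
from tuftnet import coexpr, enrich, markers, pseudobulk, qc, specificity
from tuftnet.simulate import SimConfig, generate_cohort, read_fixture

logger = logging.getLogger("tuftnet")

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the run seed and stage name."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    drop_empty: bool = False  # synthetic cohorts carry no empty droplets
    min_cells: int = 20
    max_sparsity: float = 0.99
    mito_k: float = 2.5
    mito_prefix: str = "MT-"
    k_neighbors: int | None = None  # None: min(250, n_cells // 20)
    resolution: float = 0.6
    n_pcs: int = 50
    hvg: int = 5000
    min_module_size: int = 30
    merge_height: float = 0.25
    hub_mm: float = 0.7
    hub_kim: float = 0.7
    hub_adj: float = 0.3
    aux_gs: float = 0.5
    aux_gs_p: float = 0.05
    aux_mm: float = 0.5
    n_perm_grouping: int = 10000
    n_perm_gsea: int = 1000
    da_k: int | None = None  # None: min(250, max(20, 3 * n_samples))
    da_n_pcs: int = 4
    da_sample_fraction: float = 0.1
    majority: float = 0.8
    spatial_alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_sparsity", "majority", "spatial_alpha"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def run_all(config: RunConfig, input_dir: str | Path | None = None,
            out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a dict of stage artifacts.

    With ``config.simulate`` a synthetic cohort is generated; otherwise
    ``input_dir`` must hold an MTX triplet with cell metadata. With
    ``out_dir`` set, tables are also written as TSV plus a markdown
    summary. Identical config and seed give identical outputs.
    """
    art: dict = {}
    if config.simulate:
        sim_cfg = SimConfig(seed=stage_seed(config.seed, "simulate"), **config.sim)
        adata, truth = generate_cohort(sim_cfg)
        art["sim_config"], art["truth"] = sim_cfg, truth
        target_genes = list(truth.module_members)
        driver = sim_cfg.driver_gene
    elif input_dir is not None:
        adata, truth = read_fixture(input_dir)
        art["truth"] = truth
        target_genes = truth.module_members if truth else []
        driver = "DRIVER"
    else:
        raise ValueError("either enable simulate or provide input_dir")
    logger.info("cohort: %d cells x %d genes", adata.n_obs, adata.n_vars)

    adata, report = qc.run_qc(adata, min_cells=config.min_cells,
                              max_sparsity=config.max_sparsity,
                              mito_k=config.mito_k, mito_prefix=config.mito_prefix,
                              drop_empty=config.drop_empty)
    art["qc_report"] = report
    logger.info("after QC: %d cells x %d genes", adata.n_obs, adata.n_vars)
    if driver not in adata.var_names:
        raise RuntimeError("driver gene removed by QC; cannot continue")
    target_genes = [g for g in target_genes if g in adata.var_names]

    # pan-cohort pseudo-bulk and network
    pb = pseudobulk.make_pseudobulk(adata, by="sample")
    art["pseudobulk"] = pb
    driver_expr = pb.lognorm[driver]
    net = coexpr.build_network(pb.zscore.drop(columns=[driver]))
    art["pan_network"] = net
    traits = pd.DataFrame({"driver_expr": driver_expr})
    mt = coexpr.module_trait_correlations(net.eigengenes, traits)
    art["module_trait"] = mt

    # clustering
    logtp = markers.log_tp10k(adata.X)
    hvg = cl.select_hvg(adata.X, adata.var_names,
                        n=min(config.hvg, adata.n_vars))
    hvg_idx = [adata.var_names.get_loc(g) for g in hvg]
    scores = cl.embed_pca(logtp[:, hvg_idx], n_pcs=config.n_pcs,
                          seed=stage_seed(config.seed, "pca"))
    k = config.k_neighbors or cl.default_k(adata.n_obs)
    graph = cl.snn_graph(scores, k=k)
    labels = cl.find_clusters(graph, resolution=config.resolution,
                              seed=stage_seed(config.seed, "louvain"))
    labels = cl.merge_similar_clusters(labels, logtp)
    adata.obs["cluster"] = labels
    art["cluster_labels"] = labels
    logger.info("found %d clusters", len(np.unique(labels)))

    # rare cluster: the one with maximal mean module-gene expression
    if target_genes:
        tg_idx = [adata.var_names.get_loc(g) for g in target_genes]
        mean_by_cluster = pd.DataFrame(
            np.asarray(logtp[:, tg_idx].todense()), index=labels
        ).groupby(level=0).mean().mean(axis=1)
        rare_cluster = int(mean_by_cluster.idxmax())
    else:
        rare_cluster = int(pd.Series(labels).value_counts().idxmin())
    art["rare_cluster"] = rare_cluster

    # markers + enrichment of the target set in the marker ranking
    mk = markers.hurdle_marker_test(logtp, labels, rare_cluster,
                                    gene_names=adata.var_names.tolist())
    art["markers"] = mk
    if target_genes:
        ranking = pd.Series(mk["avg_log2FC"], index=mk.index)
        art["marker_enrichment"] = enrich.preranked_gsea(
            ranking, target_genes, n_perm=config.n_perm_gsea,
            seed=stage_seed(config.seed, "gsea"))

    # hub-gene sample grouping with permutation null
    stats = coexpr.gene_statistics(pb.zscore[net.modules.index], net.eigengenes,
                                   net.modules, driver_expr, net.adjacency)
    art["pan_stats"] = stats
    mt_driver = mt["cor"]["driver_expr"].abs()
    driver_module = mt_driver.idxmax()
    art["driver_module"] = driver_module
    hubs = coexpr.hub_genes(stats, driver_module, config.hub_mm, config.hub_kim,
                            config.hub_adj)
    art["hub_genes"] = hubs
    if hubs:
        part = specificity.group_samples_by_hub_genes(pb.zscore, hubs)
        art["grouping"] = specificity.grouping_permutation_p(
            pb.zscore, part, n_perm=config.n_perm_grouping,
            seed=stage_seed(config.seed, "grouping"))

    # per-cluster pseudo-bulk; intra-cluster network in the rare cluster
    percluster = {}
    for cid in np.unique(labels):
        sub = adata[labels == cid]
        if sub.obs["sample"].nunique() < 3:
            continue
        try:
            percluster[cid] = pseudobulk.make_pseudobulk(sub, by="sample")
        except ValueError:
            continue
    art["percluster_pb"] = percluster
    aux = []
    if rare_cluster in percluster and target_genes:
        pbz = percluster[rare_cluster].zscore
        intra = coexpr.build_network(pbz.drop(columns=[driver], errors="ignore"),
                                     beta=6)
        art["intra_network"] = intra
        drv = percluster[rare_cluster].lognorm[driver]
        istats = coexpr.gene_statistics(pbz[intra.modules.index], intra.eigengenes,
                                        intra.modules, drv, intra.adjacency)
        art["intra_stats"] = istats
        tstats = istats.table.loc[istats.table.index.isin(target_genes)]
        tstats = tstats[tstats["module"] != coexpr.UNASSIGNED]
        if len(tstats):
            target_mod = tstats["module"].mode().iloc[0]
            aux = specificity.define_auxiliary_module(
                istats, target_genes, target_mod, config.aux_gs,
                config.aux_gs_p, config.aux_mm)
    art["auxiliary_module"] = aux
    if len(aux) >= 2:
        pbz_map = {cid: p.zscore for cid, p in percluster.items()}
        art["preservation"] = specificity.preservation_cor_kme(
            pbz_map, rare_cluster, aux)
        art["corr_panel"] = specificity.pairwise_correlation_panel(
            pbz_map, aux + [driver])

    # abundance modelling
    props = ab.cluster_proportions(labels, adata.obs["sample"].to_numpy())
    rare_abundance = props[rare_cluster] if rare_cluster in props else None
    art["cluster_proportions"] = props
    if rare_abundance is not None:
        art["abundance_univariate"] = ab.abundance_univariate(
            rare_abundance, pb.lognorm[driver])
        art["abundance_scan"] = ab.abundance_scan(pb.lognorm, rare_abundance)
        n_samples = adata.obs["sample"].nunique()
        k_da = config.da_k or min(250, max(20, 5 * n_samples))
        nset = ab.build_neighbourhoods(
            scores, adata.obs["sample"].to_numpy(), labels,
            k=min(k_da, adata.n_obs - 1), n_pcs=config.da_n_pcs,
            sample_fraction=config.da_sample_fraction,
            seed=stage_seed(config.seed, "neighbourhoods"))
        art["neighbourhoods"] = nset
        if "grouping" in art:
            try:
                da = ab.da_test(nset, art["grouping"].partition)
                art["da_results"] = ab.filter_majority(
                    nset, da, config.majority, config.spatial_alpha)
            except ValueError as err:
                logger.warning("differential abundance skipped: %s", err)

    if out_dir is not None:
        _write_artifacts(art, config, Path(out_dir))
    return art


def _write_artifacts(art: dict, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
    if "qc_report" in art:
        art["qc_report"].to_json(out / "qc_report.json")
    if "markers" in art:
        art["markers"].to_csv(out / "markers.tsv", sep="\t")
    if "pan_network" in art:
        art["pan_network"].modules.rename("module").to_csv(
            out / "pan_modules.tsv", sep="\t", index_label="gene")
    if "pan_stats" in art:
        art["pan_stats"].table.to_csv(out / "pan_gene_stats.tsv", sep="\t")
    if "pan_network" in art and "driver_module" in art:
        net = art["pan_network"]
        genes = net.modules.index[net.modules == art["driver_module"]]
        coexpr.export_edges(net.adjacency.loc[genes, genes]).to_csv(
            out / "driver_module_edges.tsv", sep="\t", index=False)
    if "grouping" in art:
        g = art["grouping"]
        g.partition.rename("group").to_csv(out / "sample_groups.tsv", sep="\t",
                                           index_label="sample")
    if "preservation" in art:
        art["preservation"].table.to_csv(out / "preservation.tsv", sep="\t")
    if "abundance_scan" in art:
        art["abundance_scan"].to_csv(out / "abundance_scan.tsv", sep="\t")
    if "da_results" in art:
        art["da_results"].to_csv(out / "da_results.tsv", sep="\t", index_label="nhood")
    lines = ["# tuftnet run summary", ""]
    if "qc_report" in art:
        r = art["qc_report"]
        lines.append(f"- cells in/out: {r.n_barcodes_in}/{r.n_barcodes_out}")
    if "rare_cluster" in art:
        lines.append(f"- rare (target-enriched) cluster: {art['rare_cluster']}")
    if "hub_genes" in art:
        lines.append(f"- hub genes: {', '.join(art['hub_genes'])}")
    if "grouping" in art:
        lines.append(f"- grouping permutation p: {art['grouping'].empirical_p:.4g}")
    if "abundance_univariate" in art:
        u = art["abundance_univariate"]
        lines.append(f"- driver~abundance coefficient {u['coefficient']:.3g} "
                     f"(p={u['p']:.3g})")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
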