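"""Rare-cluster abundance: moderated gene scan and neighbourhood DA.

Two directions: (i) a univariate OLS of rare-cluster abundance on driver
expression, plus a genome-wide moderated scan of expression on abundance;
(ii) kNN-neighbourhood differential abundance between low- and high-driver
samples with a density-weighted spatial FDR.
"""

import warnings

import numpy as np
import pandas as pd

from tuftnet import abundance as ab
from tuftnet import cluster as cl
from tuftnet import markers, pseudobulk
from tuftnet.simulate import SimConfig, generate_cohort

config = SimConfig(seed=0)
adata, truth = generate_cohort(config)

logtp = markers.log_tp10k(adata.X)
hvg = cl.select_hvg(adata.X, adata.var_names, n=min(5000, adata.n_vars))
scores = cl.embed_pca(logtp[:, [adata.var_names.get_loc(g) for g in hvg]],
                      n_pcs=50)
labels = cl.find_clusters(cl.snn_graph(scores, k=cl.default_k(adata.n_obs)),
                          resolution=0.6, seed=0)
rare = pd.Series(labels[truth.cell_cluster == config.rare_cluster_index]) \
    .value_counts().idxmax()

pb = pseudobulk.make_pseudobulk(adata)
props = ab.cluster_proportions(labels, adata.obs["sample"].to_numpy())
uni = ab.abundance_univariate(props[rare], pb.lognorm[config.driver_gene])
print(f"abundance ~ driver expression: coefficient {uni['coefficient']:.3g}, "
      f"p {uni['p']:.3g}")

scan = ab.abundance_scan(pb.lognorm, props[rare])
hits = scan[(scan["fdr"] < 0.05) & (scan["logFC"] > 1)]
planted = set(truth.module_members) | {config.driver_gene}
print(f"moderated scan: {len(hits)} hits at FDR < 0.05 and logFC > 1; "
      f"{sum(g in planted for g in hits.index)} are planted "
      "(module genes or the driver)")

act = truth.sample_driver_activity
groups = pd.Series(np.where(act > act.median(), "high", "low"),
                   index=act.index)
nset = ab.build_neighbourhoods(scores, adata.obs["sample"].to_numpy(), labels,
                               k=5 * config.n_samples, n_pcs=4, seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    da = ab.da_test(nset, groups)
res = ab.filter_majority(nset, da)
rare_n = res[res["majority_cluster"] == rare]
n_dep = int(((rare_n["spatial_fdr"] < 0.01) & (rare_n["logFC"] < 0)).sum())
print(f"neighbourhoods: {len(nset.counts)} built, {len(res)} pure "
      f"(majority > 0.8), {len(rare_n)} in the rare cluster, "
      f"{n_dep} significantly depleted in the low-driver group "
      "(spatial FDR < 0.01)")
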