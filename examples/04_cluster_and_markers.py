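"""Cell clustering, rare-cluster markers and marker-set enrichment.

PCA on variance-stabilised genes, shared-nearest-neighbour graph, Louvain
communities, a two-part hurdle marker test of the rare cluster against
all other cells, and preranked enrichment of the planted gene set in the
fold-change ranking.
"""

import numpy as np
import pandas as pd

from tuftnet import cluster as cl
from tuftnet import enrich, markers
from tuftnet.simulate import SimConfig, generate_cohort

config = SimConfig(seed=0)
adata, truth = generate_cohort(config)

logtp = markers.log_tp10k(adata.X)
hvg = cl.select_hvg(adata.X, adata.var_names, n=min(5000, adata.n_vars))
scores = cl.embed_pca(logtp[:, [adata.var_names.get_loc(g) for g in hvg]],
                      n_pcs=50)
graph = cl.snn_graph(scores, k=cl.default_k(adata.n_obs))
labels = cl.find_clusters(graph, resolution=0.6, seed=0)
print(f"found {len(np.unique(labels))} clusters "
      f"(planted: {config.n_clusters})")

rare_mask = truth.cell_cluster == config.rare_cluster_index
best = pd.Series(labels[rare_mask]).value_counts().idxmax()
recall = np.mean(labels[rare_mask] == best)
print(f"rare cluster recovered as cluster {best}, recall {recall:.3f}")

table = markers.hurdle_marker_test(logtp, labels, best,
                                   gene_names=adata.var_names.tolist())
print("top 5 markers (gene, p_val, avg_log2FC, pct.1, pct.2, p_val_adj):")
print(table.head(5).to_string(float_format=lambda v: f"{v:.3g}"))
sig = (table.loc[truth.module_members, "p_val_adj"] < 0.05).mean()
print(f"{sig:.0%} of planted module genes are significant markers")

res = enrich.preranked_gsea(table["avg_log2FC"], truth.module_members,
                            n_perm=1000, seed=0)
print(f"planted-set enrichment in the marker ranking: ES {res.es:.2f}, "
      f"NES {res.nes:.2f}, p {res.p:.2g}")
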