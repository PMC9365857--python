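"""Quality control and TMM-normalised pseudo-bulk aggregation.

Runs the gene/cell filters on a synthetic cohort, then sums counts per
sample and normalises: TMM factors, log2-CPM, per-gene z-scores.
"""

from tuftnet import pseudobulk, qc
from tuftnet.simulate import SimConfig, generate_cohort

adata, truth = generate_cohort(SimConfig(seed=0))
filtered, report = qc.run_qc(adata, drop_empty=False)
print(f"QC: {report.n_barcodes_in} -> {report.n_barcodes_out} cells; "
      f"{report.genes_removed} genes removed (<20 cells); "
      f"{report.cells_removed_sparsity} cells removed (sparsity > 0.99)")

pb = pseudobulk.make_pseudobulk(filtered)
print(f"pseudo-bulk: {pb.counts.shape[0]} samples x {pb.counts.shape[1]} genes")
print("TMM factors (geometric mean 1):")
print(pb.tmm.round(3).to_string())
print(f"z-score matrix: per-gene mean ~0, sd ~1; "
      f"{len(pb.constant_genes)} constant genes flagged")
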