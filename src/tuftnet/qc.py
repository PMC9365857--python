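"""Droplet, cell and gene quality-control filters.

Four filters, applied by :func:`run_qc` in a fixed order: (i) empty-droplet
removal at the inflection point of the barcode rank curve, (ii) removal of
genes expressed in fewer than ``min_cells`` cells, (iii) removal of cells
with expression sparsity above ``max_sparsity``, (iv) removal of cells
whose mitochondrial expression proportion exceeds the median by more than
``k`` median absolute deviations (upper tail only, unscaled MAD).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCReport",
    "barcode_rank_inflection",
    "filter_genes_min_cells",
    "filter_cells_sparsity",
    "filter_cells_mito",
    "run_qc",
]


class NoInflectionError(ValueError):
    """Raised when the barcode rank curve has no interior inflection."""


@dataclass
class QCReport:
    n_barcodes_in: int
    n_barcodes_out: int
    inflection_threshold: float
    genes_removed: int
    cells_removed_sparsity: int
    cells_removed_mito: int

    def __post_init__(self) -> None:
        if self.n_barcodes_out > self.n_barcodes_in:
            raise ValueError("n_barcodes_out cannot exceed n_barcodes_in")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def barcode_rank_inflection(umi_per_barcode: np.ndarray, min_barcodes: int = 100,
                            smooth_window: int = 3) -> float:
    """UMI threshold at the steepest drop of the barcode rank curve.

    The curve of log10(count) against log10(cumulative rank) is built on
    unique count values, smoothed with a short moving average, and the
    threshold is placed at the geometric midpoint of the segment with the
    steepest negative slope. Barcodes with counts strictly below the
    returned threshold are considered empty droplets.
    """
    counts = np.asarray(umi_per_barcode)
    counts = counts[counts > 0]
    if counts.size < min_barcodes:
        raise ValueError(f"need >= {min_barcodes} nonzero barcodes, got {counts.size}")
    uniq = np.unique(counts)[::-1]  # descending
    if uniq.size < 2:
        raise NoInflectionError("no inflection found: all counts equal")
    # cumulative rank: number of barcodes with count >= value
    ranks = np.cumsum([np.sum(counts == u) for u in uniq])
    logc = np.log10(uniq.astype(float))
    logr = np.log10(ranks.astype(float))
    # resample onto an even log-rank grid: slopes between raw points with
    # near-identical ranks are dominated by noise
    grid = np.linspace(logr[0], logr[-1], max(50, uniq.size))
    curve = np.interp(grid, logr, logc)
    if curve.size >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.convolve(curve, kernel, mode="same")
        half = smooth_window // 2
        sm[:half] = curve[:half]
        sm[-half:] = curve[-half:]
    else:
        sm = curve
    slope = np.diff(sm) / np.diff(grid)
    if not np.any(slope < 0):
        raise NoInflectionError("no inflection found")
    # first sustained steep excursion: the discrete low-count tail (counts
    # 2 -> 1) always ends in artefactually steep segments, so the global
    # minimum is unreliable; take the first region reaching half the
    # steepest slope and descend to its local minimum
    cutoff = 0.5 * slope.min()
    i = int(np.argmax(slope <= cutoff))
    while i + 1 < slope.size and slope[i + 1] <= slope[i]:
        i += 1
    return float(10 ** ((curve[i] + curve[i + 1]) / 2))


def _per_cell_counts(adata: AnnData) -> np.ndarray:
    return np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()


def filter_empty_droplets(adata: AnnData, **kwargs) -> tuple[AnnData, float]:
    """Remove barcodes below the barcode-rank inflection threshold."""
    totals = _per_cell_counts(adata)
    thr = barcode_rank_inflection(totals, **kwargs)
    return adata[totals >= thr].copy(), thr


def filter_genes_min_cells(adata: AnnData, min_cells: int = 20) -> AnnData:
    """Keep genes with nonzero expression in at least ``min_cells`` cells."""
    ncells = np.asarray((sp.csr_matrix(adata.X) > 0).sum(axis=0)).ravel()
    return adata[:, ncells >= min_cells].copy()


def filter_cells_sparsity(adata: AnnData, max_sparsity: float = 0.99) -> AnnData:
    """Remove cells whose fraction of zero-count genes exceeds ``max_sparsity``."""
    n_genes = adata.n_vars
    detected = np.asarray((sp.csr_matrix(adata.X) > 0).sum(axis=1)).ravel()
    sparsity = 1.0 - detected / n_genes
    return adata[sparsity <= max_sparsity].copy()


def filter_cells_mito(adata: AnnData, mito_genes: list[str], k: float = 2.5) -> AnnData:
    """Remove cells with mito proportion above median + k * MAD (unscaled MAD).

    Upper tail only: high mitochondrial content flags damaged cells. With a
    non-finite ``k`` the filter is the identity.
    """
    mito_genes = [g for g in mito_genes if g in adata.var_names]
    if not mito_genes:
        raise ValueError("empty mitochondrial gene set")
    if not np.isfinite(k):
        return adata.copy()
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, [adata.var_names.get_loc(g) for g in mito_genes]]
                      .sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(totals > 0, mito / totals, 0.0)
    med = np.median(prop)
    mad = np.median(np.abs(prop - med))
    return adata[prop <= med + k * mad].copy()


def run_qc(adata: AnnData, min_cells: int = 20, max_sparsity: float = 0.99,
           mito_k: float = 2.5, mito_prefix: str = "MT-",
           drop_empty: bool = True) -> tuple[AnnData, QCReport]:
    """Apply the four filters in order; returns the filtered data and a report."""
    n_in = adata.n_obs
    thr = 0.0
    out = adata
    if drop_empty:
        out, thr = filter_empty_droplets(out)
    g_in = out.n_vars
    out = filter_genes_min_cells(out, min_cells=min_cells)
    genes_removed = g_in - out.n_vars
    n0 = out.n_obs
    out = filter_cells_sparsity(out, max_sparsity=max_sparsity)
    removed_sparsity = n0 - out.n_obs
    mito_genes = [g for g in out.var_names if g.startswith(mito_prefix)]
    removed_mito = 0
    if mito_genes:
        n0 = out.n_obs
        out = filter_cells_mito(out, mito_genes, k=mito_k)
        removed_mito = n0 - out.n_obs
    report = QCReport(
        n_barcodes_in=n_in,
        n_barcodes_out=out.n_obs,
        inflection_threshold=thr,
        genes_removed=genes_removed,
        cells_removed_sparsity=removed_sparsity,
        cells_removed_mito=removed_mito,
    )
    return out, report
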