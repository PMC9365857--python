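"""Preranked gene set enrichment analysis.

Running-sum enrichment on a ranked gene statistic: hits advance the walk
by |stat|^weight (normalised over the set), misses retreat by 1/(N - N_hit);
the enrichment score is the extremum of the walk. Significance comes from
a gene-set-sampling null (random same-size sets), with the normalised
score NES = ES / mean(|null ES| of the same sign) and a +1-smoothed
one-tailed p-value. When several sets are tested together, p-values are
BH-adjusted across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "running_sum", "enrichment_score", "preranked_gsea",
           "gsea_multi"]


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    padj: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0

    def __post_init__(self) -> None:
        if self.es * self.nes < 0:
            raise ValueError("NES must carry the sign of ES")


def _order_stats(ranked: pd.Series) -> pd.Series:
    return ranked.sort_values(ascending=False, kind="mergesort")


def running_sum(ranked: pd.Series, gene_set, weight: float = 1.0) -> np.ndarray:
    """The enrichment walk over genes ordered by decreasing statistic."""
    ranked = _order_stats(ranked)
    hits = ranked.index.isin(set(gene_set))
    if not hits.any():
        raise ValueError("gene set does not intersect the ranking")
    if hits.all():
        raise ValueError("gene set covers the whole ranking")
    w = np.abs(ranked.to_numpy()) ** weight
    hit_inc = np.where(hits, w, 0.0)
    total = hit_inc.sum()
    if total == 0:  # all hit stats zero (possible at weight > 0): fall back to flat
        hit_inc = hits.astype(float)
        total = hit_inc.sum()
    miss_dec = np.where(hits, 0.0, 1.0 / (len(ranked) - hits.sum()))
    return np.cumsum(hit_inc / total - miss_dec)


def _extremum(walk: np.ndarray) -> float:
    """Extremum of the walk; exact ties in magnitude resolve positive."""
    hi, lo = float(walk.max()), float(walk.min())
    return hi if hi >= -lo else lo


def enrichment_score(ranked: pd.Series, gene_set, weight: float = 1.0) -> float:
    return _extremum(running_sum(ranked, gene_set, weight=weight))


def _leading_edge(ranked: pd.Series, gene_set, weight: float) -> list[str]:
    ranked = _order_stats(ranked)
    walk = running_sum(ranked, gene_set, weight=weight)
    es = _extremum(walk)
    i = int(np.argmax(walk)) if es >= 0 else int(np.argmin(walk))
    gs = set(gene_set)
    if es >= 0:
        return [g for g in ranked.index[: i + 1] if g in gs]
    return [g for g in ranked.index[i:] if g in gs]


def preranked_gsea(ranked: pd.Series, gene_set, n_perm: int = 10000,
                   weight: float = 1.0, seed: int = 0,
                   rng: np.random.Generator | None = None) -> EnrichmentResult:
    """Enrichment of one gene set in a ranked statistic.

    ``ranked`` maps gene -> real statistic; only genes present in the
    ranking contribute. The null samples random gene sets of the same
    effective size from the ranking.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ranked = _order_stats(ranked.astype(float))
    gs = [g for g in set(gene_set) if g in ranked.index]
    if not gs:
        raise ValueError("gene set does not intersect the ranking")
    es = enrichment_score(ranked, gs, weight=weight)

    names = ranked.index.to_numpy()
    stats = ranked.to_numpy()
    m = len(gs)
    null = np.empty(n_perm)
    absw = np.abs(stats) ** weight
    miss_base = 1.0 / (len(names) - m)
    for b in range(n_perm):
        pick = rng.choice(len(names), size=m, replace=False)
        hits = np.zeros(len(names), dtype=bool)
        hits[pick] = True
        inc = np.where(hits, absw, 0.0)
        tot = inc.sum()
        if tot == 0:
            inc = hits.astype(float)
            tot = float(m)
        walk = np.cumsum(inc / tot - np.where(hits, 0.0, miss_base))
        null[b] = _extremum(walk)

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        # no same-sign null scores: the observed sign itself is extreme
        nes, p = es, 1.0 / (1.0 + n_perm)
    else:
        nes = es / np.mean(np.abs(same))
        exceed = np.sum(np.abs(same) >= abs(es))
        p = (1.0 + exceed) / (1.0 + same.size)
    return EnrichmentResult(es=es, nes=float(nes), p=float(p), padj=float(p),
                            leading_edge=_leading_edge(ranked, gs, weight),
                            n_perm=n_perm)


def gsea_multi(ranked: pd.Series, gene_sets: dict[str, list],
               n_perm: int = 10000, weight: float = 1.0,
               seed: int = 0) -> pd.DataFrame:
    """Several gene sets against one ranking, BH-corrected across sets."""
    rng = np.random.default_rng(seed)
    rows = {}
    for name, gs in gene_sets.items():
        res = preranked_gsea(ranked, gs, n_perm=n_perm, weight=weight, rng=rng)
        rows[name] = {"es": res.es, "nes": res.nes, "p": res.p,
                      "leading_edge": ",".join(res.leading_edge)}
    out = pd.DataFrame(rows).T
    out["padj"] = np.maximum(multipletests(out["p"].astype(float),
                                           method="fdr_bh")[1],
                             out["p"].astype(float))
    return out
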