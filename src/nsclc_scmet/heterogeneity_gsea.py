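"""Variability-driven pathway enrichment: SD ranking + preranked GSEA.

Genes are ranked within a cell group by their expression standard
deviation (most variable first) and a weighted Kolmogorov–Smirnov-style
running-sum enrichment score (ES) asks whether a pathway's genes
concentrate at the top of that ranking.  Hits advance the running sum by
|metric|^p normalized by the total hit mass, misses retreat it by
1/(N − |S|); ES is the running-sum value of maximal absolute deviation.
Significance and NES come from a gene-sampling null: random gene sets of
matching size drawn from the ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "RankedList", "GseaResult", "sd_ranking", "enrichment_score",
    "gsea_preranked", "heterogeneity_report",
]


@dataclass
class RankedList:
    """Genes ordered by a non-negative metric, descending, ties lexicographic."""

    gene_ids: list[str]
    metric: np.ndarray
    group_id: str = ""

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if not np.all(np.isfinite(self.metric)) or np.any(self.metric < 0):
            raise ValueError("metric must be finite and >= 0")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing")


@dataclass
class GseaResult:
    pathway: str
    es: float
    nes: float
    p_value: float
    n_genes_in_list: int
    leading_edge: list[str]
    n_perm: int
    seed: int


def sd_ranking(
    m: ExpressionMatrix, cell_subset: list[str] | None = None, group_id: str = ""
) -> RankedList:
    """Rank genes by SD (ddof=1) over the given cells, descending."""
    sub = m.subset_cells(cell_subset) if cell_subset is not None else m
    if sub.n_cells < 2:
        raise ValueError("sd_ranking needs at least 2 cells")
    sd = sub.values.std(axis=1, ddof=1)
    order = sorted(range(sub.n_genes), key=lambda i: (-sd[i], sub.gene_ids[i]))
    return RankedList([sub.gene_ids[i] for i in order], sd[order], group_id)


def _running_sum(metric: np.ndarray, hit: np.ndarray, p: float) -> np.ndarray:
    """Weighted KS running profile over the list (length N)."""
    n = len(metric)
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits == n:
        # no misses (or no hits): the miss decrement is undefined; treat the
        # miss term as 0 so S = whole list gives the pure hit profile
        miss_step = np.zeros(n)
    else:
        miss_step = (~hit).astype(float) / (n - n_hits)
    w = np.abs(metric) ** p
    hit_mass = np.where(hit, w, 0.0)
    total = hit_mass.sum()
    if total == 0:
        # all hit metrics are zero (e.g. constant genes at p>0): fall back to
        # equal hit increments so the profile is still defined
        hit_mass = hit.astype(float)
        total = hit_mass.sum()
    return np.cumsum(hit_mass / total - miss_step)


_TIE_TOL = 1e-12


def _es_from_profile(profile: np.ndarray) -> tuple[float, int]:
    """(ES, extremum index): value of maximal |deviation|, earliest position.

    Equal |deviation| within 1e-12 counts as a tie (guards against the
    running sum reaching ±v at different positions with only rounding
    noise separating them) and resolves to the earliest position.
    """
    dev = np.abs(profile)
    idx = int(np.argmax(dev >= dev.max() - _TIE_TOL))
    return float(profile[idx]), idx


def enrichment_score(
    ranked: RankedList, gene_set: set[str] | list[str], weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES for one gene set: (ES, running_profile, leading_edge).

    The leading edge is the hit genes at or before the extremum for
    ES > 0, and at or after it for ES < 0.
    """
    gene_set = set(gene_set)
    hit = np.array([g in gene_set for g in ranked.gene_ids])
    if not hit.any():
        raise ValueError("gene set is disjoint from the ranked list")
    profile = _running_sum(ranked.metric, hit, weight_exponent)
    es, idx = _es_from_profile(profile)
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.gene_ids) if hit[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(ranked.gene_ids) if hit[i] and i >= idx]
    return es, profile, leading


def _null_es(
    metric: np.ndarray, set_size: int, n_perm: int, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets, vectorised."""
    n = len(metric)
    w = np.abs(metric) ** p
    miss_div = n - set_size
    es = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        pos = rng.choice(n, size=set_size, replace=False)
        hit[:] = False
        hit[pos] = True
        hit_mass = np.where(hit, w, 0.0)
        total = hit_mass.sum()
        if total == 0:
            hit_mass = hit.astype(float)
            total = float(set_size)
        miss = (~hit) / miss_div if miss_div > 0 else 0.0
        profile = np.cumsum(hit_mass / total - miss)
        es[b], _ = _es_from_profile(profile)
    return es


def gsea_preranked(
    ranked: RankedList,
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> tuple[list[GseaResult], pd.DataFrame]:
    """Run the preranked statistic for every pathway; returns (results, skipped).

    Genes absent from the ranked list are dropped from each set before the
    size filter.  NES = ES / mean(|null ES of the same sign|); the p-value
    is the add-one fraction of same-sign null scores at least as extreme.
    """
    rng = np.random.default_rng(seed)
    in_list = set(ranked.gene_ids)
    results: list[GseaResult] = []
    skipped_rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in gsc.sets.items():
        overlap = [g for g in genes if g in in_list]
        if not (min_size <= len(overlap) <= max_size):
            skipped_rows.append({
                "pathway": name, "overlap": len(overlap),
                "reason": f"overlap outside [{min_size}, {max_size}]",
            })
            continue
        es, _profile, leading = enrichment_score(ranked, overlap, weight_exponent)
        k = len(overlap)
        if k not in null_cache:
            null_cache[k] = _null_es(ranked.metric, k, n_perm, weight_exponent, rng)
        null = null_cache[k]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size:
            nes = es / np.abs(same_sign).mean()
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        else:
            nes = es / max(np.abs(null).mean(), np.finfo(float).tiny)
            p = 1.0 / (1.0 + n_perm)
        results.append(GseaResult(name, es, float(nes), float(p), k, leading, n_perm, seed))
    return results, pd.DataFrame(skipped_rows, columns=["pathway", "overlap", "reason"])


def results_table(results: list[GseaResult]) -> pd.DataFrame:
    rows = [{
        "pathway": r.pathway, "es": r.es, "nes": r.nes, "p_value": r.p_value,
        "n_genes": r.n_genes_in_list, "leading_edge_size": len(r.leading_edge),
    } for r in results]
    df = pd.DataFrame(rows, columns=["pathway", "es", "nes", "p_value", "n_genes",
                                     "leading_edge_size"])
    return df.sort_values("nes", ascending=False).reset_index(drop=True) if len(df) else df


def heterogeneity_report(
    m: ExpressionMatrix,
    labels: np.ndarray,
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-cluster SD ranking + GSEA; returns (tables per cluster, summary).

    The summary lists each cluster's top pathway by NES.
    """
    labels = np.asarray(labels)
    tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for c in np.unique(labels):
        cells = [m.cell_ids[j] for j in np.flatnonzero(labels == c)]
        ranked = sd_ranking(m, cells, group_id=str(c))
        results, _sk = gsea_preranked(
            ranked, gsc, n_perm=n_perm, weight_exponent=weight_exponent,
            seed=seed, min_size=min_size, max_size=max_size,
        )
        tab = results_table(results)
        tables[str(c)] = tab
        if len(tab):
            top = tab.iloc[0]
            summary_rows.append({
                "cluster": str(c), "top_pathway": top["pathway"],
                "nes": top["nes"], "p_value": top["p_value"],
            })
    summary = pd.DataFrame(summary_rows, columns=["cluster", "top_pathway", "nes", "p_value"])
    return tables, summary
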