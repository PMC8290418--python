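"""Weighted relative pathway-activity scoring with a label-permutation null.

The statistic: for gene ``g`` and cluster ``c`` the relative expression is

    r(g, c) = mean expression over cells in c / mean over all cells,

and a pathway P scores

    A(P, c) = Σ_{g∈P} w(g) · r(g, c) / Σ_{g∈P} w(g),

with gene weights ``w(g) = 1 / #pathways containing g`` down-weighting
genes shared across pathways.  A(P, c) > 1 marks relative upregulation of
P in cluster c.  Significance comes from shuffling the cluster label
vector across cells (cluster sizes preserved) and recomputing A; p-values
use the add-one rule p = (1 + #{A_perm ≥ A_obs}) / (1 + n_perm), so they
are never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("nsclc_scmet")


@dataclass
class PathwayActivityResult:
    score: pd.DataFrame          # pathway × cluster
    p_up: pd.DataFrame
    p_down: pd.DataFrame
    gene_weights: dict[str, float]
    relative_expression: pd.DataFrame  # gene × cluster
    genes_used: dict[str, list[str]]
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        for p in (self.p_up, self.p_down):
            vals = p.to_numpy()
            if np.any(vals <= 0) or np.any(vals > 1):
                raise ValueError("permutation p-values must lie in (0, 1]")


# ---------------------------------------------------------------------------

def relative_expression(
    m: ExpressionMatrix, labels: np.ndarray, denominator: str = "all_cells"
) -> pd.DataFrame:
    """Cluster-mean / global-mean expression ratio per gene.

    ``denominator="all_cells"`` pools every cell for the global mean (the
    primary definition); ``"cluster_means"`` averages the per-cluster means
    instead, which removes the cluster-size weighting.  Genes whose global
    mean is 0 get NaN and are excluded downstream.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("relative expression needs at least 2 clusters")
    if m.layer_tag == "counts":
        logger.warning("relative_expression on raw counts; normalize first")
    means = np.column_stack([m.values[:, labels == c].mean(axis=1) for c in clusters])
    if denominator == "all_cells":
        denom = m.values.mean(axis=1)
    elif denominator == "cluster_means":
        denom = means.mean(axis=1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom[:, None] > 0, means / denom[:, None], np.nan)
    return pd.DataFrame(r, index=m.gene_ids, columns=[str(c) for c in clusters])


def pathway_weights(gsc: GeneSetCollection, universe: set[str] | None = None) -> dict[str, float]:
    """w(g) = 1 / number of (retained) pathways containing g.

    ``universe`` restricts to genes present in the matrix after filtering;
    genes in no pathway are absent from the map.
    """
    weights = {}
    for g, n in gsc.membership_counts().items():
        if universe is None or g in universe:
            weights[g] = 1.0 / n
    return weights


def filter_pathway_genes(
    m: ExpressionMatrix,
    gsc: GeneSetCollection,
    min_mean: float = 0.0,
    max_zero_fraction: float = 0.95,
    min_genes: int = 5,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Drop low-expression / high-dropout genes per pathway, then small pathways.

    A gene is dropped when its all-cell mean is < ``min_mean`` or its
    zero fraction exceeds ``max_zero_fraction`` (and always when its mean
    is 0, since its relative expression is undefined).  Pathways left with
    fewer than ``min_genes`` genes are removed entirely.
    """
    mean = m.values.mean(axis=1)
    zero_frac = (m.values == 0).mean(axis=1)
    ok = {
        g: (mu >= min_mean) and (mu > 0) and (zf <= max_zero_fraction)
        for g, mu, zf in zip(m.gene_ids, mean, zero_frac)
    }
    kept_sets: dict[str, list[str]] = {}
    rows = []
    for name, genes in gsc.sets.items():
        surviving = [g for g in genes if ok.get(g, False)]
        rows.append({
            "pathway": name, "n_genes_in": len(genes), "n_genes_kept": len(surviving),
            "kept": len(surviving) >= min_genes,
        })
        if len(surviving) >= min_genes:
            kept_sets[name] = surviving
    if not kept_sets:
        raise ValueError("all pathways dropped by gene filters")
    report = pd.DataFrame(rows)
    filtered = GeneSetCollection(
        kept_sets, {k: gsc.descriptions.get(k, "") for k in kept_sets}
    )
    return filtered, report


def score_activity(
    r: pd.DataFrame, weights: dict[str, float], gsc_filtered: GeneSetCollection
) -> pd.DataFrame:
    """A(P,c) = Σ w(g)·r(g,c) / Σ w(g) over the pathway's retained genes."""
    scores = {}
    for name, genes in gsc_filtered.sets.items():
        w = np.array([weights[g] for g in genes])
        total = w.sum()
        if total <= 0:
            raise ValueError(f"pathway {name!r} has zero total weight")
        sub = r.loc[genes].to_numpy()
        if np.any(np.isnan(sub)):
            raise ValueError(f"pathway {name!r} contains genes with undefined r")
        scores[name] = (w[:, None] * sub).sum(axis=0) / total
    return pd.DataFrame.from_dict(scores, orient="index", columns=r.columns)


def _weight_matrix(
    gsc: GeneSetCollection, weights: dict[str, float], gene_index: dict[str, int]
) -> tuple[np.ndarray, list[str]]:
    """Row-normalized (pathway × gene) weight matrix for fast rescoring."""
    names = list(gsc.sets)
    W = np.zeros((len(names), len(gene_index)))
    for i, name in enumerate(names):
        for g in gsc.sets[name]:
            W[i, gene_index[g]] = weights[g]
        W[i] /= W[i].sum()
    return W, names


def permutation_test(
    m: ExpressionMatrix,
    labels: np.ndarray,
    gsc_filtered: GeneSetCollection,
    weights: dict[str, float],
    n_perm: int = 5000,
    seed: int = 0,
    denominator: str = "all_cells",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Permutation p-values for A(P,c); returns (score, p_up, p_down).

    Each permutation shuffles the full label vector across cells, which
    preserves cluster sizes, and recomputes every pathway score.  The
    add-one estimator keeps p in (0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    used_genes = sorted({g for genes in gsc_filtered.sets.values() for g in genes})
    sub = m.subset_genes(used_genes)
    gi = {g: i for i, g in enumerate(used_genes)}
    W, names = _weight_matrix(gsc_filtered, weights, gi)

    V = sub.values  # genes × cells
    global_mean = V.mean(axis=1)
    if np.any(global_mean == 0):
        raise ValueError("genes with zero global mean must be filtered before scoring")
    onehot = np.zeros((m.n_cells, len(clusters)))
    for k, c in enumerate(clusters):
        onehot[labels == c, k] = 1.0
    counts = onehot.sum(axis=0)

    def rescore(oh: np.ndarray) -> np.ndarray:
        means = (V @ oh) / counts
        if denominator == "all_cells":
            denom = global_mean
        else:  # cluster_means
            denom = means.mean(axis=1)
        return W @ (means / denom[:, None])

    A_obs = rescore(onehot)
    rng = np.random.default_rng(seed)
    ge = np.zeros_like(A_obs, dtype=np.int64)
    le = np.zeros_like(A_obs, dtype=np.int64)
    for _ in range(n_perm):
        # shuffling labels across cells == permuting the one-hot rows
        A_perm = rescore(onehot[rng.permutation(m.n_cells)])
        ge += A_perm >= A_obs
        le += A_perm <= A_obs
    cols = [str(c) for c in clusters]
    score = pd.DataFrame(A_obs, index=names, columns=cols)
    p_up = pd.DataFrame((1.0 + ge) / (1.0 + n_perm), index=names, columns=cols)
    p_down = pd.DataFrame((1.0 + le) / (1.0 + n_perm), index=names, columns=cols)
    return score, p_up, p_down


def compute_pathway_activity(
    m: ExpressionMatrix,
    labels: np.ndarray,
    gsc: GeneSetCollection,
    n_perm: int = 5000,
    seed: int = 0,
    min_mean: float = 0.0,
    max_zero_fraction: float = 0.95,
    min_genes: int = 5,
    denominator: str = "all_cells",
) -> PathwayActivityResult:
    """Full scoring pass: filter genes/pathways, weight, score, permute."""
    gsc_f, _report = filter_pathway_genes(m, gsc, min_mean, max_zero_fraction, min_genes)
    weights = pathway_weights(gsc_f)
    r = relative_expression(m, labels, denominator)
    score, p_up, p_down = permutation_test(
        m, labels, gsc_f, weights, n_perm=n_perm, seed=seed, denominator=denominator
    )
    return PathwayActivityResult(
        score=score, p_up=p_up, p_down=p_down, gene_weights=weights,
        relative_expression=r, genes_used=dict(gsc_f.sets),
        n_permutations=n_perm, seed=seed,
    )


def significant_pathways(
    result: PathwayActivityResult, alpha: float = 0.01, direction: str = "up"
) -> tuple[pd.DataFrame, pd.Series]:
    """Rows where the score departs from 1 significantly, plus per-cluster counts.

    Upregulated: score > 1 and p_up < alpha; downregulated: score < 1 and
    p_down < alpha.  Sorted by score descending.
    """
    if direction == "up":
        mask = (result.score > 1) & (result.p_up < alpha)
        pmat = result.p_up
    elif direction == "down":
        mask = (result.score < 1) & (result.p_down < alpha)
        pmat = result.p_down
    else:
        raise ValueError("direction must be 'up' or 'down'")
    rows = []
    for pw in result.score.index:
        for c in result.score.columns:
            if mask.loc[pw, c]:
                rows.append({
                    "pathway": pw, "cluster": c,
                    "score": result.score.loc[pw, c], "p": pmat.loc[pw, c],
                })
    table = pd.DataFrame(rows, columns=["pathway", "cluster", "score", "p"])
    if not table.empty:
        table = table.sort_values("score", ascending=False).reset_index(drop=True)
    counts = pd.Series(
        {c: int(mask[c].sum()) for c in result.score.columns}, name="n_significant"
    )
    return table, counts
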