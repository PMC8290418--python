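"""QC filtering, normalization, HVG selection, PCA, clustering and annotation.

The clustering backend is a pluggable contract: downstream stages only
need a per-cell label vector, so k-means on the reduced space (seeded) is
the default and externally computed labels can be passed through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import ExpressionMatrix

logger = logging.getLogger("nsclc_scmet")


@dataclass
class QCReport:
    axis: str  # "genes" or "cells"
    n_in: int
    n_out: int
    removal_counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float | int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in - sum(self.removal_counts.values()) != self.n_out:
            raise ValueError("QC arithmetic violated: in - removed != out")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removal_counts.items()]
        rows.append({"filter": f"total_{self.axis}_in", "removed": self.n_in})
        rows.append({"filter": f"total_{self.axis}_out", "removed": self.n_out})
        return pd.DataFrame(rows)


@dataclass
class ReducedSpace:
    """Cell × component PCA scores with variance shares."""

    scores: np.ndarray  # (n_cells, n_components)
    variance_shares: np.ndarray
    cell_ids: list[str]
    n_hvg: int
    n_components: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_shares) > 1e-12):
            raise ValueError("components must be ordered by decreasing variance share")


def filter_genes_min_cells(
    m: ExpressionMatrix, min_cells: int
) -> tuple[ExpressionMatrix, QCReport]:
    """Keep genes detected (value > 0) in at least ``min_cells`` cells."""
    if m.layer_tag != "counts":
        raise ValueError("gene filtering expects the counts layer")
    detected = (m.values > 0).sum(axis=1)
    keep = detected >= min_cells
    if not keep.any():
        raise ValueError("all genes removed by min-cells filter")
    out = ExpressionMatrix(
        m.values[keep], [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.cell_ids), m.cell_meta, m.layer_tag,
    )
    report = QCReport(
        "genes", m.n_genes, out.n_genes,
        {"min_cells": int((~keep).sum())}, {"min_cells": min_cells},
    )
    return out, report


def filter_cells_qc(
    m: ExpressionMatrix,
    min_genes_per_cell: int = 200,
    max_mito_fraction: float | None = None,
    mito_genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop low-quality cells: too few detected genes, or (optionally) a
    mitochondrial count fraction above ``max_mito_fraction``."""
    if m.layer_tag != "counts":
        raise ValueError("cell QC expects the counts layer")
    detected = (m.values > 0).sum(axis=0)
    keep = detected >= min_genes_per_cell
    removal = {"min_genes": int((~keep).sum())}
    if max_mito_fraction is not None and mito_genes:
        idx = m.gene_index()
        rows = [idx[g] for g in mito_genes if g in idx]
        lib = m.values.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, m.values[rows].sum(axis=0) / lib, 0.0)
        mito_ok = frac <= max_mito_fraction
        removal["max_mito"] = int((keep & ~mito_ok).sum())
        keep &= mito_ok
    if not keep.any():
        raise ValueError("all cells removed by QC filters")
    cols = np.flatnonzero(keep)
    out = ExpressionMatrix(
        m.values[:, cols], list(m.gene_ids), [m.cell_ids[j] for j in cols],
        m.cell_meta.iloc[cols], m.layer_tag,
    )
    report = QCReport(
        "cells", m.n_cells, out.n_cells, removal,
        {"min_genes_per_cell": min_genes_per_cell, "max_mito_fraction": max_mito_fraction},
    )
    return out, report


def normalize(m: ExpressionMatrix, method: str = "size_factor", log1p: bool = False,
              size_factors: np.ndarray | None = None) -> ExpressionMatrix:
    """Depth-correct counts by library-size factors (ratio to mean library).

    ``sf_c = library_c / mean(library)``; values are divided by ``sf_c`` so
    the mean library size is conserved.  Externally computed factors (e.g.
    pooled deconvolution ones) can be injected via ``size_factors``.
    ``method="none"`` only retags the layer.
    """
    if m.layer_tag != "counts":
        raise ValueError("normalize expects the counts layer")
    if method == "none":
        values = m.values.copy()
    elif method == "size_factor":
        if size_factors is None:
            lib = m.values.sum(axis=0)
            if np.any(lib == 0):
                raise ValueError("zero-library cell encountered; run cell QC first")
            size_factors = lib / lib.mean()
        values = m.values / np.asarray(size_factors)[None, :]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    tag = "normalized"
    if log1p:
        values = np.log1p(values)
        tag = "lognorm"
    return ExpressionMatrix(values, list(m.gene_ids), list(m.cell_ids), m.cell_meta, tag)


def select_hvg(m: ExpressionMatrix, k: int) -> list[str]:
    """Top-``k`` genes by per-gene SD (ddof=1); ties broken lexicographically."""
    if m.layer_tag == "counts":
        raise ValueError("HVG selection expects a normalized or lognorm layer")
    if k > m.n_genes:
        logger.warning("select_hvg: k=%d clamped to n_genes=%d", k, m.n_genes)
        k = m.n_genes
    sd = m.values.std(axis=1, ddof=1)
    order = sorted(range(m.n_genes), key=lambda i: (-sd[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:k]]


def reduce_pca(
    m: ExpressionMatrix, hvg: list[str], n_components: int, scale: bool = False
) -> ReducedSpace:
    """PCA on the HVG submatrix (cells as observations), sign-stabilised.

    Genes are centered (and optionally unit-scaled); each component's sign
    is fixed by forcing its largest-|loading| entry positive, so results
    are deterministic across LAPACK builds.
    """
    sub = m.subset_genes(hvg)
    x = sub.values.T  # cells × genes
    if n_components > min(len(hvg), m.n_cells):
        raise ValueError("n_components exceeds min(|hvg|, n_cells)")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance gene among HVGs; cannot scale")
        x = x / sd
    if np.allclose(x, 0):
        raise ValueError("degenerate input: all HVGs constant")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return ReducedSpace(scores, pca.explained_variance_ratio_.copy(),
                        list(m.cell_ids), len(hvg), n_components)


def cluster_cells(
    space: ReducedSpace,
    backend: str = "kmeans",
    n_clusters: int = 2,
    seed: int = 0,
    external_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Label every cell; labels densely renumbered 0..K−1 by decreasing size."""
    if backend == "external_labels":
        if external_labels is None:
            raise ValueError("external_labels backend requires labels")
        raw = np.asarray(external_labels)
    elif backend == "kmeans":
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        raw = km.fit_predict(space.scores)
    elif backend == "graph_community":
        raw = _graph_community(space.scores, seed)
    else:
        raise ValueError(f"unknown clustering backend {backend!r}")
    return _renumber_by_size(raw)


def _graph_community(scores: np.ndarray, seed: int, n_neighbors: int = 15) -> np.ndarray:
    from sklearn.neighbors import kneighbors_graph
    import igraph
    import leidenalg

    n_neighbors = min(n_neighbors, scores.shape[0] - 1)
    adj = kneighbors_graph(scores, n_neighbors=n_neighbors, mode="connectivity")
    sources, targets = adj.nonzero()
    g = igraph.Graph(n=scores.shape[0], edges=list(zip(sources.tolist(), targets.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, seed=seed
    )
    return np.asarray(part.membership)


def _renumber_by_size(raw: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(raw, return_counts=True)
    # decreasing size; ties by original label for determinism
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {uniq[i]: rank for rank, i in enumerate(order)}
    return np.asarray([mapping[v] for v in raw], dtype=int)


def annotate_clusters(
    m: ExpressionMatrix, labels: np.ndarray, markers: dict[str, list[str]]
) -> dict[int, str]:
    """Assign each cluster the cell type whose markers it expresses most.

    score(type, cluster) = mean normalized expression of the type's marker
    genes over the cluster's cells; argmax wins, exact ties (including the
    all-zero cluster) give ``"ambiguous"``.  Marker genes absent from the
    matrix are logged and skipped; no marker found at all is an error.
    """
    idx = m.gene_index()
    rows_per_type: dict[str, list[int]] = {}
    for ct, genes in markers.items():
        present = [idx[g] for g in genes if g in idx]
        missing = [g for g in genes if g not in idx]
        if missing:
            logger.warning("annotate_clusters: %s markers missing: %s", ct, missing)
        rows_per_type[ct] = present
    if not any(rows_per_type.values()):
        raise ValueError("no marker genes found in matrix")

    labels = np.asarray(labels)
    result: dict[int, str] = {}
    for c in np.unique(labels):
        cols = labels == c
        scores = {
            ct: float(m.values[np.ix_(rows, cols)].mean()) if rows else -np.inf
            for ct, rows in rows_per_type.items()
        }
        best = max(scores.values())
        winners = [ct for ct, s in scores.items() if s == best]
        result[int(c)] = winners[0] if len(winners) == 1 and best > 0 else "ambiguous"
    return result
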