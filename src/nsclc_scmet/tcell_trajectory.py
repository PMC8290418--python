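"""T-cell subtype gating, pseudotime correlation screening, TF-network assembly.

Gating uses hard thresholds on marker expression (linear normalized
scale): CD4+ T cells have CD8A < 1 and CD4 > 1; CD8+ T cells the opposite
pattern; within CD4+ cells, Tregs have FOXP3 + CD25 > 2 and T helpers
express neither FOXP3 nor CD25 (exactly 0, configurable epsilon).
Inequalities are strict, so cells sitting exactly on a threshold stay
unassigned.  CD25 is an alias of IL2RA; resolution goes through an
explicit synonym map rather than silent renaming.

The screen computes each gene's Pearson correlation with a supplied
per-cell pseudotime and keeps genes with |r| > r_min and two-sided
p < p_max (t reference distribution with n−2 df, no multiple-testing
correction for selection; a BH-adjusted column is emitted for
transparency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, RegulonTable

__all__ = [
    "GateRules", "TFNetwork", "gate_subtypes", "pseudotime_stand_in",
    "correlate_with_pseudotime", "split_by_direction", "build_tf_network",
]

DEFAULT_SYNONYMS: dict[str, list[str]] = {
    "CD4": ["CD4"],
    "CD8A": ["CD8A"],
    "FOXP3": ["FOXP3"],
    "CD25": ["CD25", "IL2RA"],
}


@dataclass
class GateRules:
    """Thresholds for the marker gates (strict inequalities throughout)."""

    cd4_min: float = 1.0
    cd8a_max: float = 1.0
    cd8a_min: float = 1.0
    cd4_max: float = 1.0
    treg_sum_min: float = 2.0
    zero_epsilon: float = 0.0  # "did not express" means value <= epsilon
    synonyms: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_SYNONYMS.items()
    })


def _resolve_marker(m: ExpressionMatrix, canonical: str, synonyms: dict[str, list[str]]) -> int:
    idx = m.gene_index()
    tried = synonyms.get(canonical, [canonical])
    for symbol in tried:
        if symbol in idx:
            return idx[symbol]
    raise KeyError(f"marker {canonical} not found; tried symbols {tried}")


def gate_subtypes(
    m: ExpressionMatrix,
    tcell_ids: list[str] | None = None,
    rules: GateRules | None = None,
) -> pd.Series:
    """Assign {CD4, CD8, Treg, Th, unassigned} per cell.

    Treg and Th are refinements of the CD4+ gate; CD4+ cells matching
    neither stay plain CD4.  Returns a Series indexed by cell_id.
    """
    rules = rules or GateRules()
    sub = m.subset_cells(tcell_ids) if tcell_ids is not None else m
    cd4 = sub.values[_resolve_marker(sub, "CD4", rules.synonyms)]
    cd8a = sub.values[_resolve_marker(sub, "CD8A", rules.synonyms)]
    foxp3 = sub.values[_resolve_marker(sub, "FOXP3", rules.synonyms)]
    cd25 = sub.values[_resolve_marker(sub, "CD25", rules.synonyms)]

    labels = np.full(sub.n_cells, "unassigned", dtype=object)
    is_cd4 = (cd8a < rules.cd8a_max) & (cd4 > rules.cd4_min)
    is_cd8 = (cd8a > rules.cd8a_min) & (cd4 < rules.cd4_max)
    labels[is_cd8] = "CD8"
    labels[is_cd4] = "CD4"
    treg = is_cd4 & (foxp3 + cd25 > rules.treg_sum_min)
    th = is_cd4 & (foxp3 <= rules.zero_epsilon) & (cd25 <= rules.zero_epsilon)
    labels[treg] = "Treg"
    labels[th] = "Th"
    return pd.Series(labels, index=pd.Index(sub.cell_ids, name="cell_id"), name="subtype")


def pseudotime_stand_in(
    m: ExpressionMatrix,
    cell_subset: list[str] | None = None,
    orientation_marker: str | None = None,
) -> pd.Series:
    """Min-max-scaled first-PC projection as a simple pseudotime.

    The sign is oriented so the orientation marker correlates
    non-negatively with the result.  This is a deliberately simple linear
    stand-in for trajectory-inference pseudotime; it recovers ordering
    exactly when the cells follow a single linear expression program.
    """
    sub = m.subset_cells(cell_subset) if cell_subset is not None else m
    if sub.n_cells < 3:
        raise ValueError("pseudotime stand-in needs at least 3 cells")
    x = sub.values.T - sub.values.T.mean(axis=0)
    if np.allclose(x, 0):
        raise ValueError("degenerate input: no variance across cells")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tau = u[:, 0] * s[0]
    if orientation_marker is not None:
        marker = sub.values[sub.gene_index()[orientation_marker]]
        if np.corrcoef(marker, tau)[0, 1] < 0:
            tau = -tau
    tau = (tau - tau.min()) / (tau.max() - tau.min())
    return pd.Series(tau, index=pd.Index(sub.cell_ids, name="cell_id"), name="tau")


def correlate_with_pseudotime(
    m: ExpressionMatrix,
    tau: pd.Series,
    r_min: float = 0.2,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson r against pseudotime with exact-t two-sided p.

    Selected ⇔ |r| > r_min and p < p_max.  Constant genes get r = 0,
    p = 1.  Columns: gene_id (index), r, p, p_bh, direction, selected.
    """
    tau = tau.loc[list(m.cell_ids)]
    t = tau.to_numpy(dtype=float)
    n = len(t)
    if n < 4:
        raise ValueError("correlation screen needs at least 4 cells")
    if np.std(t) == 0:
        raise ValueError("pseudotime is constant")
    x = m.values
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    st = np.sqrt((tc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / (sx * st)
    constant = sx == 0
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", over="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(constant, 1.0, np.minimum(p, 1.0))
    p_bh = multipletests(p, method="fdr_bh")[1]
    selected = (np.abs(r) > r_min) & (p < p_max)
    df = pd.DataFrame({
        "r": r,
        "p": p,
        "p_bh": p_bh,
        "direction": np.where(r >= 0, "positive", "negative"),
        "selected": selected,
    }, index=pd.Index(m.gene_ids, name="gene_id"))
    return df


def split_by_direction(screen: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition selected genes by sign of r → (positive, negative) lists."""
    sel = screen[screen["selected"]]
    pos = sel.index[sel["r"] > 0].tolist()
    neg = sel.index[sel["r"] < 0].tolist()
    return pos, neg


@dataclass
class TFNetwork:
    """TF→target edges restricted to screened genes."""

    nodes: pd.DataFrame  # index gene_id; columns is_tf, r
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes.index)
        for tf, target in self.edges:
            if tf not in node_set or target not in node_set:
                raise ValueError(f"edge ({tf}, {target}) endpoint not in nodes")
            if not self.nodes.loc[tf, "is_tf"]:
                raise ValueError(f"edge source {tf} is not a TF")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for gene, row in self.nodes.iterrows():
            g.add_node(gene, is_tf=bool(row["is_tf"]), r=float(row["r"]))
        g.add_edges_from(self.edges)
        return g


def build_tf_network(
    selected_genes_with_r: pd.Series, regulons: RegulonTable
) -> TFNetwork:
    """Restrict the regulon catalog to screened genes.

    Nodes are the selected genes (with their screen r as an attribute);
    TF nodes are selected genes present in the TF catalog; edges are
    regulon edges whose endpoints are both selected and whose source is a
    TF node.  An empty network is a valid result.
    """
    selected = set(selected_genes_with_r.index)
    tf_nodes = selected & regulons.tfs
    edges = [
        (tf, target)
        for tf, target, _src in regulons.edges
        if tf in tf_nodes and target in selected
    ]
    nodes = pd.DataFrame({
        "is_tf": [g in tf_nodes for g in selected_genes_with_r.index],
        "r": selected_genes_with_r.to_numpy(dtype=float),
    }, index=selected_genes_with_r.index.copy())
    nodes.index.name = "gene_id"
    return TFNetwork(nodes, edges)
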