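"""Synthetic data generators with known ground truth.

Three generators mirror the statistical structure the downstream stages
assume:

* :func:`simulate_sc` — clustered, dropout-heavy negative-binomial counts
  with cluster-specific pathway programs planted as fold changes, for the
  pathway-activity scoring and heterogeneity stages.
* :func:`simulate_trajectory` — cells along a latent differentiation
  pseudotime with monotone trend genes, null genes, and T-cell gating
  markers (CD4, CD8A, FOXP3, IL2RA) whose programs realise all four gated
  subtypes.
* :func:`simulate_survival` — an expression cohort whose hazards follow a
  known sparse linear predictor, with calibrated uniform censoring, for
  the penalized-Cox screen and risk-model stages.

All randomness comes from :class:`numpy.random.Generator` seeded with the
spec's ``seed`` (PCG64), so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ClinicalTable, ExpressionMatrix, GeneSetCollection

__all__ = [
    "SCSimSpec", "TrajSimSpec", "SurvSimSpec",
    "simulate_sc", "simulate_trajectory", "simulate_survival",
]


# ---------------------------------------------------------------------------
# Clustered single-cell counts with planted pathway programs
# ---------------------------------------------------------------------------

@dataclass
class SCSimSpec:
    """Study conditions for the clustered count simulation.

    Defaults are the conditions of the planted-pathway recovery study:
    3 clusters of 500 cells, 2000 genes partitioned into 20 pathways of 50
    genes with 10% shared genes, and 5 (pathway, cluster) pairs carrying a
    2-fold upregulation.
    """

    n_clusters: int = 3
    cells_per_cluster: list[int] = field(default_factory=lambda: [500, 500, 500])
    n_genes: int = 2000
    n_pathways: int = 20
    genes_per_pathway: int = 50
    overlap_fraction: float = 0.1
    planted_effects: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 0, 2.0), (1, 1, 2.0), (2, 2, 2.0), (3, 0, 2.0), (4, 1, 2.0)]
    )
    base_mean: float = 1.0
    dispersion: float = 0.5  # NB size parameter; smaller = more overdispersed
    dropout_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if len(self.cells_per_cluster) != self.n_clusters:
            raise ValueError("cells_per_cluster length must equal n_clusters")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathway partition exceeds n_genes")
        for p, c, f in self.planted_effects:
            if not (0 <= p < self.n_pathways and 0 <= c < self.n_clusters):
                raise ValueError(f"planted effect ({p},{c}) out of range")
            if f < 1:
                raise ValueError("planted fold_change must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0,1)")


def simulate_sc(spec: SCSimSpec) -> tuple[ExpressionMatrix, GeneSetCollection, pd.DataFrame]:
    """Draw clustered NB counts with planted pathway fold changes.

    Counts are NB(mean, dispersion) per gene/cluster; genes of a planted
    pathway have their mean multiplied by ``fold_change`` in the planted
    cluster.  Dropout then zeroes entries independently, so the ratio of
    cluster means is preserved in expectation.  Pathways are built by
    partitioning the first ``n_pathways * genes_per_pathway`` genes, then
    appending ``ceil(overlap_fraction * genes_per_pathway)`` genes borrowed
    from other pathways so some genes have weight < 1 downstream.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    # disjoint cores
    core = [
        list(range(p * spec.genes_per_pathway, (p + 1) * spec.genes_per_pathway))
        for p in range(spec.n_pathways)
    ]
    n_shared = int(np.ceil(spec.overlap_fraction * spec.genes_per_pathway))
    members: list[list[int]] = []
    for p in range(spec.n_pathways):
        others = np.concatenate([core[q] for q in range(spec.n_pathways) if q != p]) \
            if spec.n_pathways > 1 else np.array([], dtype=int)
        borrowed = (
            rng.choice(others, size=n_shared, replace=False).tolist()
            if n_shared > 0 and others.size else []
        )
        members.append(core[p] + borrowed)

    gsc = GeneSetCollection(
        {f"PW{p:02d}": [gene_ids[i] for i in members[p]] for p in range(spec.n_pathways)},
        {f"PW{p:02d}": "synthetic pathway" for p in range(spec.n_pathways)},
    )

    # per-gene, per-cluster means
    mean = np.full((spec.n_genes, spec.n_clusters), spec.base_mean, dtype=float)
    truth_rows = []
    for p, c, f in spec.planted_effects:
        if f > 1.0:
            mean[members[p], c] *= f
            truth_rows.append({"pathway": f"PW{p:02d}", "cluster": c, "fold_change": f})
    truth = pd.DataFrame(truth_rows, columns=["pathway", "cluster", "fold_change"])

    n_cells = int(sum(spec.cells_per_cluster))
    labels = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)
    size = spec.dispersion
    counts = np.empty((spec.n_genes, n_cells), dtype=float)
    for c in range(spec.n_clusters):
        cols = labels == c
        mu = mean[:, c][:, None]
        p_nb = size / (size + mu)
        counts[:, cols] = rng.negative_binomial(size, p_nb, size=(spec.n_genes, cols.sum()))
    if spec.dropout_rate > 0:
        counts[rng.random(counts.shape) < spec.dropout_rate] = 0.0

    cell_ids = [f"C{j:05d}" for j in range(n_cells)]
    meta = pd.DataFrame({
        "sample_id": [f"p{labels[j]}" for j in range(n_cells)],
        "cluster_id": labels,
    })
    m = ExpressionMatrix(counts, gene_ids, cell_ids, meta, layer_tag="counts")
    return m, gsc, truth


# ---------------------------------------------------------------------------
# T-cell trajectory with gating markers
# ---------------------------------------------------------------------------

@dataclass
class TrajSimSpec:
    """Study conditions for the pseudotime / gating simulation.

    Trend genes follow ``a + b·τ + N(0, σ²)`` with τ ~ Uniform(0,1); with the
    defaults (b = 1, σ = 0.5) the expected Pearson |r| with τ is ≈ 0.5.
    Marker programs place every cell in exactly one gated region: CD4
    helper-like cells carry FOXP3 = CD25 = 0 exactly (structural zeros),
    Tregs carry FOXP3 + CD25 > 2, CD8 cells invert the CD4/CD8A pattern.
    """

    n_cells: int = 300
    n_trend_up: int = 100
    n_trend_down: int = 50
    n_null_genes: int = 150
    trend_effect: float = 1.0
    noise_sd: float = 0.5
    baseline: float = 2.0
    subtype_probs: dict[str, float] = field(
        default_factory=lambda: {"CD4": 0.25, "CD8": 0.35, "Treg": 0.15, "Th": 0.25}
    )
    marker_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")
        probs = np.array(list(self.subtype_probs.values()))
        if np.any(probs <= 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("subtype_probs must be positive and sum to 1")


MARKER_GENES = ("CD4", "CD8A", "FOXP3", "IL2RA")


def simulate_trajectory(spec: TrajSimSpec) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Generate trajectory data; returns (matrix, pseudotime_truth, subtype_truth).

    The CD25 marker is emitted under its HGNC symbol IL2RA so that gating
    exercises the synonym map.  Values are on a linear normalized-like
    scale (clipped at 0), matching the scale on which the gating
    thresholds 1 and 2 are meaningful.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    tau = rng.random(n)

    names = list(spec.subtype_probs)
    subtype = rng.choice(names, size=n, p=[spec.subtype_probs[k] for k in names])

    n_trend = spec.n_trend_up + spec.n_trend_down
    signs = np.concatenate([np.ones(spec.n_trend_up), -np.ones(spec.n_trend_down)])
    trend = (
        spec.baseline
        + signs[:, None] * spec.trend_effect * tau[None, :]
        + rng.normal(0, spec.noise_sd, size=(n_trend, n))
    )
    null = spec.baseline + rng.normal(0, spec.noise_sd, size=(spec.n_null_genes, n))

    # marker programs: high ~ U(1.5, 3), low ~ U(0, 0.5), mid ~ U(0.3, 0.8)
    def high():
        return rng.uniform(1.5, 3.0)

    def low():
        return rng.uniform(0.0, 0.5)

    markers = np.zeros((4, n))  # CD4, CD8A, FOXP3, IL2RA
    for j, st in enumerate(subtype):
        if st == "CD8":
            markers[0, j], markers[1, j] = low(), high()
            markers[2, j], markers[3, j] = low(), low()
        else:  # CD4 lineage
            markers[0, j], markers[1, j] = high(), low()
            if st == "Treg":
                markers[2, j] = rng.uniform(1.2, 2.0)
                markers[3, j] = rng.uniform(1.2, 2.0)
            elif st == "Th":
                markers[2, j] = markers[3, j] = 0.0  # structural zeros
            else:  # unspecialized CD4
                markers[2, j] = rng.uniform(0.3, 0.8)
                markers[3, j] = rng.uniform(0.3, 0.8)
    if spec.marker_noise_sd > 0:
        noise = rng.normal(0, spec.marker_noise_sd, size=markers.shape)
        positive = markers > 0
        markers[positive] = np.maximum(markers[positive] + noise[positive], 1e-6)

    values = np.clip(np.vstack([trend, null, markers]), 0.0, None)
    gene_ids = (
        [f"TREND_UP{i:03d}" for i in range(spec.n_trend_up)]
        + [f"TREND_DN{i:03d}" for i in range(spec.n_trend_down)]
        + [f"NULL{i:03d}" for i in range(spec.n_null_genes)]
        + list(MARKER_GENES)
    )
    cell_ids = [f"T{j:04d}" for j in range(n)]
    meta = pd.DataFrame({"sample_id": ["traj"] * n})
    m = ExpressionMatrix(values, gene_ids, cell_ids, meta, layer_tag="normalized")
    idx = pd.Index(cell_ids, name="cell_id")
    return m, pd.Series(tau, index=idx, name="tau"), pd.Series(subtype, index=idx, name="subtype")


def trend_truth(spec: TrajSimSpec) -> pd.DataFrame:
    """Ground-truth table of trend genes and their slope signs."""
    rows = [{"gene_id": f"TREND_UP{i:03d}", "sign": 1} for i in range(spec.n_trend_up)]
    rows += [{"gene_id": f"TREND_DN{i:03d}", "sign": -1} for i in range(spec.n_trend_down)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival cohort with known linear predictor
# ---------------------------------------------------------------------------

@dataclass
class SurvSimSpec:
    """Study conditions for the survival cohort simulation.

    Defaults are the parameter-recovery fixture: n = 500 samples, 50 genes,
    true coefficients (−0.197, −0.261, 0.185, 0.191) on the first four
    genes, exponential baseline hazard 0.001 / day (median survival ≈ 2
    years at x = 0) and a 30% censoring target.
    """

    n_samples: int = 500
    n_genes: int = 50
    true_beta: dict[str, float] = field(
        default_factory=lambda: {
            "MAP3K8": -0.197, "HERPUD1": -0.261, "GAPDH": 0.185, "DNAJB4": 0.191,
        }
    )
    baseline_hazard: float = 0.001
    censor_fraction_target: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if len(self.true_beta) > self.n_genes:
            raise ValueError("true_beta support exceeds n_genes")
        if not (0 <= self.censor_fraction_target < 1):
            raise ValueError("censor_fraction_target must be in [0,1)")


def simulate_survival(
    spec: SurvSimSpec,
) -> tuple[pd.DataFrame, ClinicalTable, pd.Series]:
    """Simulate (expression samples × genes, clinical table, true beta).

    Expression is standard normal per gene.  Event times are exponential
    with rate ``baseline_hazard * exp(xᵀβ)``; censoring times are
    Uniform(0, c_max) with c_max calibrated by bisection so the realized
    censored fraction is within ±5% (absolute) of the target.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes

    named = list(spec.true_beta)
    gene_ids = named + [f"BG{i:03d}" for i in range(g - len(named))]
    X = rng.standard_normal((n, g))
    beta = np.zeros(g)
    beta[: len(named)] = [spec.true_beta[k] for k in named]
    lin = X @ beta
    rate = spec.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)

    if spec.censor_fraction_target == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        u = np.maximum(rng.random(n), 1e-12)  # censoring quantiles, fixed across calibration
        lo, hi = 1e-9, float(t_event.max()) * 1e4

        def frac_censored(c_max: float) -> float:
            return float(np.mean(u * c_max < t_event))

        target = spec.censor_fraction_target
        if frac_censored(hi) > target + 0.05:
            raise ValueError("censoring target unreachable: too low for this cohort")
        c_max = hi
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac_censored(mid) > target:
                lo = mid
            else:
                hi = mid
            c_max = mid
            if abs(frac_censored(c_max) - target) <= 0.01:
                break
        realized = frac_censored(c_max)
        if abs(realized - target) > 0.05:
            raise ValueError(
                f"censoring calibration failed: realized {realized:.3f} vs target {target:.3f}"
            )
        t_cens = u * c_max
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"), columns=gene_ids)
    clin = ClinicalTable(pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(sample_ids, name="sample_id"),
    ))
    return expr, clin, pd.Series(beta, index=gene_ids, name="beta")
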