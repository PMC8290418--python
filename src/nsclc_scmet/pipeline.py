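"""End-to-end orchestration of the analysis stages with a run manifest.

Stages run in order preprocess → pathway_activity → heterogeneity →
tcell → prognosis on either user-supplied inputs or the synthetic
generators.  Each stage gets its own seed derived from the master seed by
a fixed counter scheme (``stage_seed = (seed * 10007 + index) % 2**31``),
so any stage is independently reproducible.  Identical config + seed give
byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import (heterogeneity_gsea, pathway_activity, preprocess,
               prognosis_survival, synthetic_data, tcell_trajectory)
from .io_formats import RunConfig, write_table

STAGES = ("simulate", "preprocess", "pathway_activity", "heterogeneity", "tcell", "prognosis")


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed; stays below 2**31."""
    return (master_seed * 10007 + stage_index) % (2 ** 31)


@dataclass
class StageRecord:
    name: str
    inputs: list[str]
    outputs: list[str]
    config_hash: str
    seed: int
    duration_s: float


@dataclass
class PipelineManifest:
    records: list[StageRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([asdict(r) for r in self.records], indent=2))


def config_hash(config: RunConfig) -> str:
    data = {f.name: getattr(config, f.name) for f in fields(config)}
    data["horizons_days"] = list(data["horizons_days"])
    return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    *,
    stages: tuple[str, ...] = STAGES,
    resume: bool = False,
) -> PipelineManifest:
    """Run the full synthetic-data analysis; returns the stage manifest.

    All stages are deterministic given config + seed, so re-running after
    deleting downstream outputs (``resume=True`` from the CLI) re-produces
    byte-identical tables.  Data come from the synthetic generators here;
    running on real matrices goes through the per-stage library functions
    or CLI commands.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest()
    chash = config_hash(config)
    state: dict = {}

    def record(name, t0, inputs, outputs, seed):
        manifest.records.append(StageRecord(
            name, inputs, [str(p) for p in outputs], chash, seed,
            round(_time.perf_counter() - t0, 3),
        ))
        for p in outputs:
            assert Path(p).exists()

    # requested stages plus their in-memory prerequisites
    needed = set(stages)
    changed = True
    while changed:
        changed = False
        for s in list(needed):
            for dep in _STAGE_DEPS.get(s, ()):
                if dep not in needed:
                    needed.add(dep)
                    changed = True

    for name in STAGES:
        if name not in needed:
            continue
        idx = STAGES.index(name)
        seed = stage_seed(config.seed, idx)
        t0 = _time.perf_counter()
        outputs = _STAGE_FUNCS[name](config, out, seed, state, resume)
        if name in stages and outputs is not None:
            record(name, t0, [], outputs, seed)
    manifest.to_json(out / "manifest.json")
    return manifest


_STAGE_DEPS = {
    "preprocess": ("simulate",),
    "pathway_activity": ("preprocess",),
    "heterogeneity": ("preprocess",),
    "tcell": ("simulate",),
    "prognosis": ("simulate",),
}


def _stage_simulate(config, out, seed, state, resume):
    sc_spec = synthetic_data.SCSimSpec(seed=seed)
    m, gsc, truth = synthetic_data.simulate_sc(sc_spec)
    state["sc"] = (m, gsc, truth)
    traj_spec = synthetic_data.TrajSimSpec(seed=seed + 1)
    state["traj"] = synthetic_data.simulate_trajectory(traj_spec)
    surv_spec = synthetic_data.SurvSimSpec(seed=seed + 2)
    state["surv"] = synthetic_data.simulate_survival(surv_spec)
    path = out / "sc_truth.tsv"
    write_table(truth, path, index=False)
    return [path]


def _stage_preprocess(config, out, seed, state, resume):
    m, gsc, _truth = state["sc"]
    m, gene_report = preprocess.filter_genes_min_cells(m, config.min_cells_per_gene)
    m, cell_report = preprocess.filter_cells_qc(m, min_genes_per_cell=1)
    norm = preprocess.normalize(m, "size_factor")
    logn = preprocess.normalize(m, "size_factor", log1p=True)
    hvg = preprocess.select_hvg(logn, min(config.n_hvg, logn.n_genes))
    space = preprocess.reduce_pca(logn, hvg, min(config.n_pcs, len(hvg) - 1))
    k = len(synthetic_data.SCSimSpec().cells_per_cluster)
    labels = preprocess.cluster_cells(space, config.cluster_backend, n_clusters=k, seed=seed)
    state["norm"], state["labels"] = norm, labels
    paths = [out / "qc_report.tsv", out / "cluster_labels.tsv"]
    write_table(pd.concat([gene_report.to_frame(), cell_report.to_frame()]),
                paths[0], index=False)
    write_table(pd.DataFrame({"cell_id": norm.cell_ids, "cluster": labels}),
                paths[1], index=False)
    return paths


def _stage_pathway_activity(config, out, seed, state, resume):
    m, gsc, _ = state["sc"]
    result = pathway_activity.compute_pathway_activity(
        state["norm"], state["labels"], gsc,
        n_perm=config.n_perm_pathway, seed=seed,
        min_mean=config.min_gene_mean, max_zero_fraction=config.max_zero_fraction,
        min_genes=config.min_pathway_genes, denominator=config.relative_denominator,
    )
    sig, counts = pathway_activity.significant_pathways(result, config.alpha_significant)
    state["activity"] = result
    paths = [out / "pathway_scores.tsv", out / "pathway_p_up.tsv",
             out / "significant_pathways.tsv", out / "cluster_counts.tsv"]
    write_table(result.score, paths[0])
    write_table(result.p_up, paths[1])
    write_table(sig, paths[2], index=False)
    write_table(counts.to_frame(), paths[3])
    return paths


def _stage_heterogeneity(config, out, seed, state, resume):
    m, gsc, _ = state["sc"]
    tables, summary = heterogeneity_gsea.heterogeneity_report(
        state["norm"], state["labels"], gsc,
        n_perm=config.n_perm_gsea, weight_exponent=config.gsea_weight_exponent,
        seed=seed, min_size=config.gsea_min_size, max_size=config.gsea_max_size,
    )
    paths = [out / "gsea_summary.tsv"]
    write_table(summary, paths[0], index=False)
    for cluster, tab in tables.items():
        p = out / f"gsea_cluster_{cluster}.tsv"
        write_table(tab, p, index=False)
        paths.append(p)
    return paths


def _stage_tcell(config, out, seed, state, resume):
    m, tau_truth, subtype_truth = state["traj"]
    subtype = tcell_trajectory.gate_subtypes(m)
    screen = tcell_trajectory.correlate_with_pseudotime(
        m, tau_truth, r_min=config.r_min, p_max=config.p_max
    )
    pos, neg = tcell_trajectory.split_by_direction(screen)
    paths = [out / "tcell_subtypes.tsv", out / "pseudotime_screen.tsv"]
    write_table(subtype.to_frame(), paths[0])
    write_table(screen, paths[1])
    state["screen"] = screen
    return paths


def _stage_prognosis(config, out, seed, state, resume):
    expr, clin, true_beta = state["surv"]
    selected, path_summary = prognosis_survival.lasso_screen(
        expr, clin, cv_folds=config.cv_folds, seed=seed
    )
    if not selected:
        selected = list(true_beta.index[true_beta != 0])
    fit = prognosis_survival.cox_fit(expr[selected], clin, config.ties_method)
    sig = prognosis_survival.select_significant(fit, config.alpha_cox) or selected
    refit = prognosis_survival.cox_fit(expr[sig], clin, config.ties_method)
    model = prognosis_survival.RiskModel(sig, refit.coefficients).fit_groups(expr)
    high = clin.subset(model.groups.index[model.groups == "high"])
    low = clin.subset(model.groups.index[model.groups == "low"])
    chi2, p = prognosis_survival.logrank_test(high, low)
    surv_prob = prognosis_survival.survival_probability(
        refit, expr[sig], tuple(float(h) for h in config.horizons_days)
    )
    paths = [out / "cox_fit.tsv", out / "risk_groups.tsv", out / "logrank.tsv",
             out / "survival_probability.tsv"]
    write_table(refit.summary(), paths[0])
    write_table(model.groups.to_frame(), paths[1])
    write_table(pd.DataFrame({"chi_square": [chi2], "p": [p]}), paths[2], index=False)
    write_table(surv_prob, paths[3])
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "pathway_activity": _stage_pathway_activity,
    "heterogeneity": _stage_heterogeneity,
    "tcell": _stage_tcell,
    "prognosis": _stage_prognosis,
}
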