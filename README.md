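# nsclc-scmet

Single-cell metabolic and immune analysis of non-small-cell lung cancer
(NSCLC), packaged as a tested, reusable pipeline. It targets the questions a
tumor single-cell RNA-seq study asks once malignant and immune cells have been
identified: which metabolic pathways are reprogrammed in which malignant cell
clusters, which pathways drive within-tumor expression heterogeneity, how
T-cell subtypes distribute along a differentiation trajectory and which genes
track it, and whether trajectory-associated genes carry prognostic information
in bulk survival cohorts.

## What it computes

**Weighted pathway activity.** For gene *g* and cluster *c*, relative
expression is the ratio of cluster-mean to all-cell-mean expression,
r(g,c) = mean_c(g) / mean_all(g). A pathway *P* scores

    A(P,c) = Σ_{g∈P} w(g)·r(g,c) / Σ_{g∈P} w(g),   w(g) = 1 / #pathways containing g,

so promiscuous genes shared across pathways are down-weighted. Significance
comes from shuffling cluster labels across cells (5000 permutations by
default) with add-one p-values; a pathway is called upregulated in a cluster
when A > 1 and the permutation p < 0.01.

**Heterogeneity GSEA.** Genes are ranked within a cluster by expression SD
(descending) and a self-contained preranked GSEA (weighted running-sum ES,
gene-sampling null, NES = ES / mean same-sign null |ES|) asks which pathways
concentrate among the most variable genes.

**T-cell gating and trajectory screen.** Hard marker gates on the linear
normalized layer: CD4+ T cells have CD8A < 1 and CD4 > 1 (CD8+ the opposite);
within CD4+, Tregs have FOXP3 + CD25 > 2 and T helpers express neither marker
(CD25 resolves to IL2RA through an explicit synonym map). A per-gene Pearson
screen against pseudotime keeps genes with |r| > 0.2 and p < 0.05, split by
sign, and intersects them with TRRUST/ORTI-style TF→target regulons to build
a transcriptional regulatory network.

**Prognostic signature.** An L1-penalized Cox screen (CV partial-likelihood
deviance, min rule) feeds a multivariate Newton–Raphson Cox fit
(Breslow/Efron ties). The linear risk score Σ βᵢ·xᵢ — for example the
published four-gene signature −0.197·MAP3K8 − 0.261·HERPUD1 + 0.185·GAPDH +
0.191·DNAJB4 — is median-split into high/low-risk groups compared by
Kaplan–Meier curves and the log-rank test, with IPCW time-dependent AUC and
Breslow-baseline survival probabilities at 1, 2 and 4 years.

Every stage is exercised end-to-end on synthetic data with known ground
truth: planted pathway fold changes in dropout-heavy negative-binomial
counts, a latent pseudotime with monotone trend genes and gateable marker
programs, and a survival cohort whose hazards follow a known sparse linear
predictor.

## Worked example

```python
import numpy as np
from nsclc_scmet import synthetic_data as sd, preprocess as pp, pathway_activity as pa

m, pathways, truth = sd.simulate_sc(sd.SCSimSpec(seed=1))   # 2000 genes x 1500 cells
labels = m.cell_meta["cluster_id"].to_numpy()
m, _ = pp.filter_genes_min_cells(m, 3)
norm = pp.normalize(m, "size_factor")
res = pa.compute_pathway_activity(norm, labels, pathways, n_perm=1000, seed=2)
sig, counts = pa.significant_pathways(res, alpha=0.01)
print(counts.to_dict())
print(truth[["pathway", "cluster"]].to_records(index=False))
```

prints

```
{'0': 2, '1': 2, '2': 2}
[('PW00', 0) ('PW01', 1) ('PW02', 2) ('PW03', 0) ('PW04', 1)]
```

six significant (pathway, cluster) pairs at α = 0.01, containing all five
planted 2-fold programs (the sixth arises from genes shared between an
affected and an unaffected pathway — exactly the promiscuity the 1/n weights
damp but cannot remove).

The same flow is available from the shell:

```bash
nsclc-sc simulate sc --seed 1 --out data/
nsclc-sc score-pathways --matrix data/matrix.tsv --labels data/labels.tsv \
    --gmt data/pathways.gmt --n-perm 5000 --seed 2 --out scores/
nsclc-sc run --seed 1 --out pipeline_out/     # full synthetic pipeline
```

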