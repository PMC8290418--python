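# Methods

This note documents the models implemented in `nsclc_scmet`, the defaults
and why they were chosen, what the synthetic generators emulate (and do
not), and the numerical decisions a maintainer would want written down.

## Preprocessing

Counts matrices are held genes × cells throughout; readers transpose dense
files on request. Gene filtering keeps genes detected (> 0) in at least 3
cells; cell QC keeps cells with ≥ 200 detected genes (a conventional
threshold — the QC criteria are configurable, and the mitochondrial-fraction
filter is off unless a mitochondrial gene list is supplied). Normalization
divides each cell by its library-size factor sf_c = library_c /
mean(library), which conserves the mean library and leaves within-cell gene
proportions untouched; externally computed factors (e.g. pooled
deconvolution) can be injected. The downstream activity score only needs
depth correction, which is why plain size factors are the default rather
than a heavier normalization.

Highly variable genes are the top k (default 3000) by per-gene SD with the
n−1 denominator, computed on the log1p-normalized layer; ties break
lexicographically so selection is deterministic. PCA (default 16 components)
centers genes and fixes each component's sign by forcing its
largest-|loading| entry positive, making scores reproducible across LAPACK
builds. Clustering is a pluggable contract — downstream stages need only a
label vector — defaulting to seeded k-means on the reduced space, with a
Leiden graph-community backend and an external-labels passthrough; labels
are renumbered 0..K−1 by decreasing cluster size. Cluster annotation assigns
each cluster the cell type whose marker genes have the highest mean
normalized expression; exact ties (including all-zero clusters) are labelled
"ambiguous" rather than guessed.

## Weighted pathway activity

Relative expression r(g,c) is the cluster mean divided by the mean over all
cells pooled. A configuration switch offers the mean-of-cluster-means
denominator instead (the two differ when cluster sizes are unequal); pooled
is the default because it is the direct reading of the ratio's definition.
Scoring runs on the *linear* normalized layer: the statistic is a ratio of
means, and taking logs first would change the estimand.

Per-pathway gene filters drop genes with all-cell mean below `min_mean`
(default 0, so only identically-zero genes, whose ratio is undefined) or
zero fraction above `max_zero_fraction` (default 0.95, a dropout guard);
pathways retaining fewer than 5 genes are removed. Weights w(g) are the
reciprocal of the number of retained pathways containing g, and
A(P,c) = Σ w·r / Σ w.

The permutation test shuffles the full cluster-label vector across cells
(preserving cluster sizes) and rescores all pathways; with the one-hot
label matrix this is a single matrix product per permutation, so the
default 5000 permutations on ~2000 genes × 1500 cells take seconds.
P-values use the add-one estimator p = (1 + #{A_perm ≥ A_obs}) / (1 + n_perm)
(and ≤ for the down-side), which is conservative and never exactly zero.
"Significantly upregulated" means A > 1 and p_up below α = 0.01; a second
α = 0.05 is kept for display masking.

## Heterogeneity GSEA

The ranking metric is per-gene SD (n−1) within a cell group, sorted
descending with lexicographic tie-break. The enrichment score is the
classic weighted Kolmogorov–Smirnov running sum: hits advance by
|metric|^p / Σ_hits |metric|^p (p = 1 by default, matching the weighted
statistic used by standard preranked tools), misses retreat by 1/(N−|S|),
and ES is the running-sum value of maximal |deviation|. Two degenerate
cases are defined explicitly: a set covering the whole list has no miss
decrement (pure hit profile, ES = 1), and an all-zero hit mass falls back
to equal hit increments. The extremum tie-break takes the earliest
position, with equality judged at 1e-12 so floating-point noise cannot
flip which of two analytically-equal deviations is chosen.

Because the input is a preranked list, the null is gene-sampling: n_perm
(default 1000) random same-size sets drawn from the list, cached per set
size. NES divides ES by the mean |null ES| of matching sign, and the
p-value is the add-one fraction of same-sign nulls at least as extreme.
Sets are size-filtered to [5, 500] after dropping genes absent from the
list.

## T-cell gating, pseudotime screen, TF network

Gating thresholds are strict inequalities — a cell sitting exactly on a
boundary is left unassigned (or non-Treg) — and "did not express" means
exactly 0 on the normalized layer (an epsilon is configurable). CD4+ cells
that qualify as neither Treg nor Th remain plain CD4; the subtype gates
therefore partition cells into {CD4, CD8, unassigned} with {Treg, Th}
refining CD4. Marker symbols resolve through an explicit, user-editable
synonym map (CD25 → IL2RA), never by silent aliasing.

Trajectory inference itself is out of scope: pseudotime is an input
contract, with a deliberately simple stand-in (min-max-scaled first-PC
projection, sign-oriented by a chosen marker) that recovers orderings
exactly for a single linear program. The screen computes each gene's
Pearson r against τ, with the two-sided p from the exact t reference
(t = r·√(n−2)/√(1−r²)); selection uses the raw |r| > 0.2 and p < 0.05
cutoffs, with a Benjamini–Hochberg column emitted for transparency but not
used to select. Constant genes get r = 0, p = 1. The TF network restricts
regulon edges to screened genes with a catalogued-TF source; screen r is
carried as a node attribute and a networkx export is provided.

## Prognostic signature

The multivariate Cox model is fitted by Newton–Raphson on the partial
likelihood with step-halving, converging at gradient norm < 1e-8 within 50
iterations; standard errors come from the inverse observed information and
per-gene significance from the Wald z. Breslow tie handling is the default
(simplest, and what the grid-search oracle reproduces); Efron is available.
Non-convergence (e.g. monotone likelihood under separation) sets a flag and
is treated as unreliable downstream. The linear predictor is max-shifted
before exponentiation; the shift cancels exactly in the likelihood,
gradient and Hessian.

The penalized screen delegates the L1 coefficient path to coxnet and
chooses λ by k-fold (default 10) cross-validated partial-likelihood
deviance (Verweij–van Houwelingen form), minimum rule, with folds
stratified on the event indicator; a fold's path may terminate early, so
only λ values covered by every fold compete. λ = 0 is the unpenalized
limit and selects all genes by construction.

Risk scores are the plain linear predictor Σ βᵢxᵢ with no intercept;
expression is used unstandardized by default (a flag enables z-scoring)
because published signature coefficients are defined on the reported
expression scale. The median split sends scores strictly above the median
to "high". Kaplan–Meier curves and the two-group log-rank test delegate to
lifelines; time-dependent AUC is the cumulative-cases/dynamic-controls
IPCW estimator from scikit-survival. Absolute survival uses the Breslow
baseline cumulative hazard from the fit, S(t|x) = exp(−Ĥ0(t)·e^{xᵀβ}),
with horizons past the last event carried forward with a warning; default
horizons are 365/730/1460 days. Nomogram-style outputs are tables
(predicted probabilities), not drawings.

## Synthetic data: what it emulates, what it does not

`simulate_sc` draws negative-binomial counts (shared dispersion 0.5, base
mean 1) for 3 clusters × 500 cells and 2000 genes partitioned into 20
pathways of 50 genes with 10% borrowed genes (so weights < 1 occur), then
zeroes entries independently with probability 0.3. Five (pathway, cluster)
pairs carry a 2-fold mean increase — the planted truth the scoring must
recover. Because dropout is independent of cluster, the ratio of cluster
means is preserved in expectation. Not emulated: batch effects, doublets,
ambient RNA, gene-specific dispersion, or depth profiles of any particular
instrument — passing tests show the statistic recovers planted fold
changes under overdispersion and dropout, not that it is robust to
structured artefacts.

`simulate_trajectory` places 300 cells uniformly on τ ∈ [0,1]; 100 genes
rise and 50 fall linearly with slope 1 and Gaussian noise σ = 0.5, giving
an expected |r| ≈ 0.5 against τ (sd of U(0,1) is ≈ 0.289), which is the
operating point at which the screen's recall and false-positive rate are
assessed; 150 genes are pure noise. Marker programs place each cell
unambiguously in one gated region (structural zeros for Th cells, sums
> 2.4 for Tregs) with small multiplicative noise on positive values, so
gating accuracy near 100% is expected by construction — the test verifies
the gate logic, not marker biology.

`simulate_survival` draws standard-normal expression for 500 samples × 50
genes, exponential event times with rate 0.001·e^{xᵀβ} (median survival
≈ 2 years at x = 0, a plausible advanced-NSCLC scale) and true β =
(−0.197, −0.261, 0.185, 0.191) on four named genes — the published
signature magnitudes used as simulation truth. Censoring is
Uniform(0, c_max) with c_max calibrated by bisection to a 30% censored
fraction (±5% enforced, error if unreachable). Proportional hazards hold
exactly by construction; the recovery tests therefore measure estimator
quality, not model misspecification.

## Verification choices and problem sizes

Hand-worked fixtures pin the core arithmetic exactly (pathway score
19/18 and 17/18; Pearson r = 0.8 with p ≈ 0.104 at df 3; Cox β̂ = −ln2/2
on three subjects; log-rank χ² = 49/17). Brute-force oracles — a
double-loop pathway scorer, a running-sum ES enumerator, a risk-set
partial-likelihood maximized by bounded scalar search, an event-time
log-rank tabulation — are implemented independently in the tests and
compared at 1e-12/1e-10/1e-4 as appropriate. Statistical checks run at
deliberately modest sizes chosen to keep the suite fast while leaving wide
power margins: 10 seeds for planted-pathway power and null calibration
(1000 permutations each), 25 seeds for Cox/lasso recovery, 200 replicates
for p-value-calibration checks.

The absolute-survival check compares the Breslow-based Ŝ(median t | x)
against the analytic exponential-model survival at n = 1000, evaluated at
the quartile profiles of the true linear predictor. Tail profiles are
deliberately excluded there: the error at extreme x is dominated by
e^{xᵀ(β̂−β)}, i.e. by coefficient sampling noise, and would measure β̂
variance rather than the baseline-hazard estimator the check targets.

## Known limitations

- Clustering does not reproduce any specific Seurat/t-SNE pipeline; labels
  are a contract, and published cluster counts will not be reproduced
  bit-for-bit.
- The pseudotime stand-in is linear; branching trajectories require an
  externally supplied τ.
- The GSEA p-value floor is 1/(n_perm+1); no multilevel refinement of
  extreme p-values is attempted.
- The gating scale assumes thresholds 1 and 2 are meaningful on the linear
  normalized layer; data normalized differently need rescaled rules.
- Survival utilities assume right-censoring only and proportional hazards;
  no competing risks.
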