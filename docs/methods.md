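# Methods

## Preprocessing

Raw UMI counts (genes × cells) pass three stages, each a distinct
`ExpressionMatrix` stage with enforced invariants:

1. **QC** — a gene is *detected* in a cell when its raw count is strictly
   positive; cells with fewer than `min_detected` (default 1000) detected
   genes are removed. A cell with exactly 1000 detected genes is kept. The
   filter is idempotent and preserves gene set and cell order.
2. **Log transform** — `log2(UMI + 1)`, entrywise.
3. **Z-scores** — per gene across cells, with the *sample* SD (divisor
   n−1). Genes constant across cells have no defined z-score and are
   dropped by default (`constant_gene_policy="drop"`); the `"zero"` policy
   keeps them as all-zero rows instead, exempted from the unit-SD invariant.

Matrices are stored gene × cell; the decomposition algorithms view cells as
row vectors over genes and transpose internally.

Interaction networks are read from SIF (plain 2/3-column and the extended
tab-separated dialect, whose trailing columns are ignored). The interaction
type column does not enter edge identity, so the graph is the union over
all interaction types; edges are undirected, unweighted, deduplicated, and
self-loops are dropped (a self-interaction cannot contribute to
connectivity between genes). Matrix and network are restricted to their
common gene set before detection; z-scoring happens **before** this
restriction, so each gene is standardized against all cells using its full
measured context.

## The decomposition model

With Y the cells × genes z-score matrix, each module k is a rank-1 term
a_k b_kᵀ whose loading support S_k induces a connected subgraph of the PPI
network. For fixed S the least-squares optimal term is the leading singular
triplet of Y[:, S]; we compute it as the top eigenpair of the support Gram
matrix (Y[:,S]ᵀY[:,S]), which is exact, deterministic, and fast for the
small supports of interest. The loading is unit-norm with the sign fixed by
Σb ≥ 0 (ties broken on the first nonzero coefficient), and the activity
a = Y[:,S] b carries the scale.

The **residual error** of a module is the Frobenius norm of Y minus its
rank-1 term (the term is zero outside S), which obeys the identity
residual² + σ₁(Y[:,S])² = ‖Y‖²_F. Because the full-matrix norm dominates,
residuals of competing modules are numerically close; they are a ranking
statistic, not an absolute goodness-of-fit.

### Search

Minimizing the residual over connected subgraphs is NP-hard, so the search
is greedy: start from a seed gene, repeatedly add the graph neighbor of the
current support whose inclusion most decreases the residual, stop when the
best relative gain falls below `min_gain` or the support reaches
`max_size`. Ties break lexicographically by gene id, making the search
fully deterministic. `detect_modules` restarts the greedy search from the
`n_seeds` best-ranked unclaimed seeds per round, keeps the lowest-residual
module, optionally deflates (subtracts the fitted term), and repeats K
times. Reported residuals are always recomputed against the original,
un-deflated matrix so modules from different rounds are comparable.

**Seed ranking.** After per-gene z-scoring every gene has variance exactly
one, so variance cannot rank seeds. Seeds are instead ranked by *neighbor
co-expression*: the sum over a gene's PPI neighbors of the squared Pearson
correlation on the current (possibly deflated) matrix. Genes inside a
co-activated connected module stand out on this score, and it remains
informative after deflation, where residual variances differ.

**Stopping gain.** `min_gain` defaults to 1e-4 (relative decrease in
residual per added gene). On UMI count data this default deserves care:
per-cell sequencing-depth variation is not removed by the log + z-score
pipeline and induces a weak positive correlation between *all* genes, so
depth-driven gains can exceed 1e-4 and the support may grow past the true
module. For count-level analyses we therefore recommend, and use in the
examples, `min_gain = 5e-4`, which sits above the typical depth-driven gain
yet far below the gain from a genuine module gene (~5e-3 in the regimes
tested). The idealized Gaussian-noise regime keeps the 1e-4 default.

**Deflation and the global residual.** With deflation the overall fit is
the sum of the terms actually subtracted, and `global_residual` is the norm
of what remains — by construction never larger than the first module's
residual. Without deflation the modules were all fit to the same matrix, so
their raw sum can double-count overlapping supports; `global_residual` is
then computed after jointly refitting the activities by least squares with
the loadings held fixed, which restores the same guarantee.

`brute_force_best_module` enumerates every connected induced subgraph up to
`max_size` (an ESU-style enumeration with a hard budget) and exists as the
independent optimality oracle for the greedy search; on 50 random 8–12-node
graphs the multi-seed greedy search reaches the exhaustive optimum's
residual within 1% in ≥ 90% of trials (measured: 45–50/50 across
generator seeds).

### Downstream summaries

`top_cells` ranks cells by signed module activity (descending, ties by cell
order). `marker_trend` takes, per cell, the maximum log expression over a
gene set (e.g. a module's zinc-finger genes), bins cells into equal-count
bins along a marker gene (e.g. *FABP4*), and reports per-bin means with
normal-approximation 95% CIs plus the Spearman correlation between
per-cell max and marker across all cells.

## Phenotype integration

Spearman correlations throughout use average ranks for ties — important
because single-cell zeros create heavy ties — and pairwise-complete
observations where phenotype values are missing. `phenotype_vectors`
requires ≥ 3 contributing clones per phenotype and records zero-variance
genes as missing. `project_to_cells` requires a configurable floor
(default 10) on the gene intersection and records cells with constant
profiles as missing, with a warning.

`compare_cluster_projections` runs a one-way ANOVA of projection scores
between clusters within each day and applies Bonferroni across **all**
(day × phenotype) tests: FWER = min(1, m·p). Cells are treated as
independent observations; note that chance rank overlap between a noise
correlation vector and a real cluster-specific program can reach
significance under this assumption (demonstrated in
`examples/02_phenotype_projection.py`).

Clone clustering is k-medoids (PAM) on Euclidean distances with a
deterministic BUILD initialization, Voronoi refinement and seeded random
restarts; k is chosen from 2–10 by maximal average silhouette width (ties
to the smaller k), warning when the best silhouette is below 0.3.
Subclustering is average-linkage hierarchical clustering on correlation
distance, cut to a requested number of groups (default five; with 35
clones, average group size seven). Distance metric and linkage are package
choices, declared here rather than inherited from any reference analysis.

The extreme-clone comparison defines "most extreme" as the largest
projection from the midpoint of the two cluster centroids along the
centroid-difference axis, on each cluster's own side. The `n_extreme`
(default 7) most extreme clones per cluster enter a per-phenotype one-way
ANOVA with Bonferroni correction across phenotypes; a selected clone
missing a phenotype value is replaced by the next most extreme (logged).
With `n_extreme` equal to the cluster size the procedure reduces exactly to
a whole-cluster ANOVA.

Donor effects in clonal profiles are handled by per-subject mean-centering
of log expression (`subject_center`) — a deliberately simple surrogate for
model-based batch normalization, adequate for removing between-subject
offsets before clustering.

## Synthetic data

The generator produces the three input types with serialized ground truth:

* **PPI graphs** — each planted support is made connected by a random
  spanning tree plus extra within-module edges
  (`within_module_edge_prob = 0.3`), over Erdős–Rényi background edges
  (`background_edge_prob = 0.01`, average degree ≈ 3 at 300 genes).
* **UMI counts** — latent log2-mean = baseline (3.0 ⇒ ~8 UMI) plus the sum
  of planted rank-1 terms with a_k ~ N(0, activity_sd) and positive
  loadings (loading_scale × U(0.8, 1.2), a co-activated complex); counts
  are negative binomial with size 5 (overdispersed, the regime the z-score
  pipeline must survive — Poisson would be too easy) and lognormal
  per-cell library factors (σ = 0.3).
* **Clonal data** — clones split into two clusters shifted by
  `cluster_separation` SD on 50 marker genes; each phenotype reads out one
  gene program's latent per-clone activity t ~ N(0,1) as
  effect_size · t + N(0,1), with program genes sharing t (default effect
  size 2 SD, default program size 20).
* `simulate_zscore_matrix` provides the idealized estimator-level regime:
  planted rank-1 signal plus unit Gaussian noise, re-standardized per gene.

Defaults (300 genes, 300 cells, 35 clones, one 10-gene module with unit
activity SD and unit-scale loadings) define a detectable-but-noisy regime.
What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene-length or GC biases, or dropout beyond what the NB law with
library-size variation produces. Passing recovery tests therefore
demonstrates correctness of the estimator and search under the model's own
assumptions, not robustness to every real-data artifact.

## Measured behavior (all recomputed by `scripts/acceptance.py`)

Problem sizes were chosen to make each quantity stable yet quick to
recompute: 200 random matrix/support pairs for the residual identity
(max relative deviation ~1e-16), 50 small-graph trials for
greedy-vs-exhaustive, 40 simulations (100 genes × 300 cells, 10-gene
module) for support recovery, 100 nested support pairs for monotonicity
(0 violations), 1000 null clone simulations for the projection ANOVA
family-wise error rate, 100 reps at a 1-SD shift with 50 cells per cluster
for its power, a 40-clone two-blob simulation for k-medoids model
selection, 35 clones in 5 groups for subclustering, and 400 cells for the
marker trend.

## Known limitations

* The greedy search has no optimality guarantee; the exhaustive oracle
  bounds the gap only at small scale.
* Residual-based ranking compares modules on the same matrix; residuals
  from different datasets are not comparable.
* Cell-level ANOVA on projections ignores within-cluster correlation
  structure; its p-values are anti-conservative when cells share latent
  programs not captured by the cluster labels.
* k-medoids with BUILD initialization is deterministic but can lodge in a
  local optimum; seeded restarts mitigate, not eliminate, this.
* The QC threshold semantics ("fewer than N detected genes") and the
  z-score-before-network-restriction ordering are fixed package
  conventions; analyses sensitive to either should say so explicitly.
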