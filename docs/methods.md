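# Methods

This note documents the statistical models, the defaults and why they were
chosen, the synthetic-data generator's assumptions, and the package's known
limitations.

## Scope and containers

The pipeline operates on a genes × cells UMI `CountMatrix` (sparse integer
counts plus barcode-keyed metadata: sample, group ∈ {Ctrl, DKD, DM, ARB,
SGLT2i, HKC}, cell type), a `GeneCatalog` of per-gene flags (mitochondrially
encoded, mito-mRNA, MANG, TF, SLC family), `GeneSetCollection`s carried as
Broad-dialect GMT, and a ligand-receptor table. Gene identifiers are
case-sensitive symbols with no alias resolution; MatrixMarket files are
1-based on disk and 0-based in memory. The bundled murine mitochondrial
catalog lists the 37 mtDNA-encoded genes (13 mRNAs, 2 rRNAs, 22 tRNAs);
only the 13 mRNAs are observable in polyA-primed UMI data and define the
PMEM statistic.

## Normalization and QC

Normalization is `ln(1 + count/total × scale)` with scale 10⁴. PMEM is the
percentage of a cell's counts on the 13 mito-mRNAs; group contrasts of PMEM
per cell type use the two-sided rank-sum test.

Doublet scoring follows the artificial-nearest-neighbour scheme: `pN·n`
artificial doublets are synthesized as averages of two cells' *linear*
normalized profiles — a droplet that pools two cells' transcripts sits at
(approximately) the library-size-weighted average of their concentration
vectors, so the averaging must happen on the linear scale, not the log
scale. The merged set is log-transformed, reduced by PCA (`dims`, default
10 here; the conventional 1–30 sweep is the caller's choice), and each real
cell's pANN is the artificial fraction among its `k = max(1, round(pK ·
merged_n))` Euclidean neighbours. Calls take the top `expected_rate`
quantile (default 7.5 %, the usual 10x loading rate). The reported tuning
values 0.1/0.18 are interpreted as pK neighbourhood fractions (they lie in
pK's conventional range); pN defaults to 0.25. Whether to retain doublets
in any compartment is caller policy, not hard-coded.

## Per-cell pathway scores

**GSVA.** Each gene's expression is summarized across cells by a kernel
CDF estimate (Gaussian kernel, bandwidth s/4; a Poisson kernel is available
for raw counts but is not the default since scoring operates on normalized
data). Per cell, genes are ranked by that statistic (ties broken by gene
id), given symmetric rank weights |p/2 − rank|^τ with τ = 1, and a weighted
KS-like random walk yields the score; the default statistic is the
max-diff form (largest positive plus largest negative deviation), bounded
in [−1, 1]. A set containing every gene of the matrix carries no ranking
information and scores 0 by convention. Zero-variance genes get statistic 0
rather than crashing.

**ssGSEA.** Per cell, genes are ranked by expression; the score is the sum
over ranks of (weighted in-set ECDF − uniform out-set ECDF) with weight
rank^α, α = 0.25. Normalization by the global (max − min) is on by default;
both modes are exposed because published analyses differ silently on this
point.

**Cell-cycle scores.** Additive module scores: mean of signature genes
minus mean of `n_ctrl = 100` control genes drawn per expression bin
(`n_bins = 25`), seeded. Phase is the argmax of the S and G2M scores when
either is positive, else G1.

## State discovery

The two-group comparison of pathway scores is the two-group special case of
the empirical-Bayes moderated linear model: per-feature sample variances s²
with d residual df are shrunk to s̃² = (d₀s₀² + d·s²)/(d₀ + d), with the
prior (d₀, s₀²) estimated by moment-matching the scaled-F distribution of
the s² (trigamma inversion of the variance of log s²). The moderated t has
d₀ + d df; p-values are BH-adjusted. A pathway is significant when adjusted
p < 0.05 and |Δscore| > 0.5 (the score difference plays the role of the
log-fold-change in this model). As d₀ → 0 the statistic reduces exactly to
the pooled two-sample t, which is the closed-form oracle used in tests.
Robust/trended variance options are deliberately omitted: the analysis fits
group contrasts only.

Cells are re-clustered on the significant pathway scores: feature-wise
standardization, PCA to `dims`, a shared-nearest-neighbour graph (k = 20,
Jaccard weights, pruned below 1/15 — the cited toolchain's defaults), and
modularity community detection at the given `resolution` with a fixed seed
(42). `dims`/`resolution` are per-cell-type inputs (the published analysis
tabulates them per type; resolution 0.1 is the common default), not
outputs. If more than two clusters emerge, all significantly
disease-enriched clusters are pooled as DDC to keep the contract total.

Dominance labelling: per cluster, the fraction of each sample's cells in
the cluster; an unpaired two-sided t-test compares the Ctrl and DKD
samples' fractions; clusters with higher disease-group mean and p < 0.05
are DDC, the rest HDC; with no significant cluster the cell type is left
unclassified. The labelling is invariant to cluster relabelling.

## Differential expression, ESDEGs, enrichment

Gene-level contrasts use the two-sided Mann-Whitney test (exact null for
groups of ≤ 8, tie-corrected normal approximation otherwise) with log2 fold
change of de-logged means (pseudocount 1, preserving antisymmetry), and the
dual rule raw p < 0.05, |log2FC| > 0.5. Both raw and BH-adjusted columns
are always emitted because gene-level calls conventionally use raw p while
pathway-level calls use FDR.

The ESDEG partition removes MANGs first, then splits the significant genes
of DA1 (Ctrl-HDC vs DKD-DDC) and DA2 (DKD-HDC vs DKD-DDC) into
intersection, DA1-exclusive, and DA2-exclusive (= ESDEG) sets. Cell types
with fewer than 100 exclusive genes (in either comparison — the published
rule quantifies only the exclusive counts) are flagged discarded.
Over-representation uses the upper-tail hypergeometric p with BH adjustment
and a top-20 cut; the universe is the caller's (recommended: genes detected
in ≥ 3 cells of the analyzed type). Fold-change concordance between the two
contrasts is summarized by Pearson r and a QR-based least-squares line.

## Pseudotime

The published analysis used a discriminative-dimension tree-embedding
(DDRTree) engine; this package substitutes a reduced principal tree with
the same contract: 2-component PCA of standardized ESDEG expression,
k-means with `n_centroids = 5` (seeded), minimum spanning tree over the
centroids, orthogonal projection of every cell onto its nearest tree edge,
and pseudotime as geodesic distance from the root along the tree. The
semi-supervision enters through the root rule: `hdc_max` roots the tree at
the leaf whose cells are most health-dominant (health as origin);
`pc1_min` is the unsupervised fallback. Identical cells yield a
single-node tree with pseudotime 0. HDC/DDC pseudotime distributions are
compared with a two-sided unpaired t-test plus kernel-density summaries.

## Cell-cell communication

Cluster ensemble expression is the 25 %-trimmed mean per gene. For a
ligand-receptor row, l and r are the ligand level in the source and the
receptor level in the target (multi-subunit complexes: geometric mean, zero
if any subunit is absent), and the communication probability is the Hill
saturation l·r/(K_h + l·r) with K_h = 0.5 — the published tool's model;
both constants are configurable. Significance: cluster labels are permuted
`n_perm = 100` times and p = (1 + #{permuted ≥ observed})/(1 + n_perm);
rows with p < 0.05 are retained and summed into per-cluster
incoming/outgoing strengths. No minimum-cells filter is imposed. The
protein-network smoothing step of the original tool requires an external
interaction database and is out of scope; probabilities are computed on
the expression matrix directly. A retained row is a DCCP when its receptor
is an ESDEG of the target's cell type (incoming) or its ligand an ESDEG of
the source's (outgoing).

## Regulons and the cascade

Regulon inference regresses each non-TF gene on the TF panel with random
forests (100 trees, √-feature sampling). Importances are GENIE3-style
*unnormalized* variance reductions on unit-variance targets — sklearn's
normalized importances are incomparable across target genes — and a
minimum leaf size of 5 % of cells keeps deep trees from explaining noise
genes' variance, which otherwise saturates the importance signal when the
TF panel is small. Cells are canonically ordered before fitting so the
result cannot depend on input cell order. The top `top_k_targets`
importances form the candidate regulon. Motif-based pruning is replaced by
a pluggable prior table (tf, target, NES): candidates are intersected with
the prior's targets and regulons with prior NES ≤ 3.0 are dropped; without
a prior, regulons are co-expression-only and labelled as such (the multi-GB
motif ranking databases are not a reasonable dependency for this package).

AUCell activity is the trapezoidal area under the recovery curve of regulon
genes among the top ⌈top_fraction · p⌉ ranks (default 0.05; ties broken by
one seeded gene permutation), normalized by the maximal achievable area —
invariant to any monotone transform of a cell's expression. Differential
regulon activity reuses the moderated test with the p < 0.01, top-50 rule.

The cascade joins ESDEG receptors to TFs when |Spearman ρ| ≥ `rho_min`
(default 0.3) with BH-adjusted p < 0.05 over all candidate pairs, and TFs
to their regulon targets with Spearman-annotated edges; TFs with no
surviving target are pruned together with their receptor edges. Spearman is
computed on normalized expression. `rho_min` and its multiplicity
correction are the module's main free parameters; the receptor→TF linkage
rule is this package's operationalization of the qualitative published
criterion.

## Bulk integration

TPM = count/length normalized to 10⁶ per sample. The deconvolution
signature is the per-subcluster mean (de-logged normalized expression) over
the union of top-10 markers of each HDC/DDC subcluster. Proportions are
estimated by non-negative least squares on the shared genes with post-hoc
simplex renormalization — deterministic, dependency-free, and exact on
noiseless mixtures, replacing the ν-SVR core of the popular tool; a
rank-deficient signature triggers a flagged pseudo-inverse fallback. Label
transfer scores each query cell by Spearman correlation to every reference
cell over the union of pairwise reference markers; the per-label score is
the 0.8-quantile of correlations to that label's cells (the cited
method's aggregation), the argmax wins, and a score gap < 0.05 flags low
confidence. The iterative fine-tuning loop of the original method is
omitted.

## The synthetic-data generator

Counts are negative binomial: gene baselines λ_g ~ LogNormal(1, 1) (≈ 3000
UMI per 400-gene cell — shallow-but-realistic droplet depth), per-gene
inverse dispersions r_g ~ LogNormal(0.7, 0.5), per-cell size factors
LogNormal(0, 0.3). Design: 2 groups × 4 replicate samples (the study's
4 + 4 animals), 3 cell types × 30 cells per sample by default, 13
mito-mRNAs with a ×3 baseline boost (PMEM ≈ 8–10 %), 240
mitochondria-associated genes organized into 40 pathway sets of 8.

Each cell carries a latent disease progression t ∈ [0, 1]:
Beta(0.15c, 0.85c) in the health-dominant state and Beta(0.85c, 0.15c) in
the disease-dominant state with concentration c = 10, so the states are
well-separated but continuous (t doubles as the planted pseudotime). 40 %
of pathway sets are shifted, alternating up/down, by log2_shift·t with
log2_shift = 3; down-shifted programs start from an elevated healthy
baseline, because a program can only visibly switch off if it is expressed
in health. The disease state holds 85 % of DKD cells and 15 % of Ctrl
cells. These effect sizes place the simulation in the regime the modeled
disease exhibits — where the bulk of mitochondrial pathways pass the dual
significance rule and the disease state is strongly group-enriched — while
remaining attainable at a few hundred cells; they were fixed once at design
time.

Doublets (7.5 % by default) are *sums* of two distinct same-sample cells'
counts — droplets pool transcripts — and are planted heterotypic
(different cell types) where possible, since homotypic doublets are
expression-indistinguishable and would make untestable ground truth. The
planted cascade expresses the ligand in the source cell type; in target
cells a latent activity u couples receptor, TF and the 10 target genes
monotonically (8-fold swing, moderate dispersion, and a count floor — a
mostly-zero gene carries no co-expression signal). The receptor baseline
scales with the source's mean ligand level, closing the
ligand → receptor → TF → target chain. Bulk mixtures are
proportion-weighted sums of per-type mean profiles with log-normal noise.

What the generator does **not** emulate: ambient RNA, batch effects beyond
sample-level size factors, gene-gene correlation outside the planted
programs, zero-inflation beyond the NB law, and realistic gene-set overlap
structure. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the assumed noise model, not performance on
real tissue.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale — hundreds of cells, 400
genes, 40 pathway sets, 20-seed replication for every stochastic claim —
chosen so the full suite completes in a few minutes on one CPU. Ties in
every per-cell ranking are broken by gene-id lexicographic order (scorers)
or one seeded permutation (AUCell); all clustering, k-means, forest and
permutation seeds are explicit arguments; BH adjustment is used for every
multiplicity correction; the trigamma inversion uses Newton iteration from
x = 0.5 + 1/y. Degenerate inputs (constant features, zero-variance genes,
all-identical cells, empty gene sets, zero-total cells) return defined
values or raise typed validation errors rather than propagating NaNs.

## Known limitations

* The moderated model assumes independent cells; pathway scores of cells
  from the same animal are correlated, so its p-values are optimistic —
  the dominance call deliberately re-aggregates to per-sample fractions
  before testing.
* The principal-tree pseudotime has a fixed 2-PC embedding and 5 centroids;
  strongly branched topologies need more centroids and are untested here.
* Communication probabilities are computed per ligand-receptor pair;
  pathway aggregation simply sums retained pairs.
* Without a motif prior, regulons are purely co-expression-based and
  inherit the usual confounding of co-regulation with co-expression.
* NNLS deconvolution has no outlier-robust loss; heavy-tailed bulk noise
  will bias proportions.
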