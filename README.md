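# mitostate

Discovery and explanation of mitochondria-driven cell states in kidney
single-cell RNA-seq.

## The problem

In diabetic kidney disease (DKD), mitochondrial dysfunction does not hit all
renal cell types equally — within a single cell type, some cells remain
metabolically healthy while others have tipped into a disease program.
`mitostate` implements, as one coherent and tested pipeline, the analysis
strategy that finds these two subpopulations and explains them:

1. **QC** — per-cell percentage of mitochondrially encoded mRNA
   (PMEM = 100 × counts on the 13 mtDNA-encoded mRNAs / total counts),
   doublet scoring by the proportion of artificial nearest neighbours
   (pANN), and one-vs-rest rank-sum marker finding.
2. **Per-cell pathway activity** — GSVA (kernel-CDF random-walk statistic,
   Gaussian kernel with bandwidth s/4, symmetric rank weights |p/2 − rank|^τ)
   and ssGSEA (summed weighted-ECDF difference, weight rank^α with α = 0.25)
   over a collection of mitochondria-associated gene sets, plus additive
   cell-cycle module scores.
3. **State discovery** — an empirical-Bayes moderated two-group test on
   pathway scores (posterior variance s̃² = (d₀s₀² + d s²)/(d₀ + d), with
   (d₀, s₀²) from moment-matching the scaled-F law of sample variances);
   cells are re-clustered on the significant pathways (PCA → shared-nearest-
   neighbour graph, k = 20, Jaccard weights → modularity communities), and
   each cluster is labelled **DDC** (disease-dominant) when its per-sample
   fraction is significantly higher in the disease group (unpaired t-test),
   otherwise **HDC** (health-dominant).
4. **ESDEGs** — Wilcoxon differential expression for the two contrasts
   DA1 (Ctrl-HDC vs DKD-DDC) and DA2 (DKD-HDC vs DKD-DDC); after removing
   mitochondria-associated nuclear genes (MANGs), genes exclusive to DA2 are
   the ESDEGs.  Hypergeometric over-representation and fold-change
   correlation complete the stage.
5. **Pseudotime** — a principal tree (minimum spanning tree over k-means
   centroids in 2-PC space of ESDEG expression) rooted at the most
   health-dominant leaf; the HDC/DDC pseudotime distributions are compared
   by a t-test.
6. **Cell-cell communication** — Hill-saturated probabilities
   l·r/(K_h + l·r) of 25 %-trimmed-mean ligand/receptor expression between
   HDC/DDC-split clusters, with a label-permutation significance test, and
   selection of pathways whose receptor (incoming) or ligand (outgoing) is
   an ESDEG (DCCPs).
7. **Regulatory cascade** — random-forest co-expression regulons
   (GENIE3-style unnormalized importances; optional motif prior with the
   NES > 3.0 rule), AUCell regulon activity (area under the recovery curve
   among the top-ranked genes), moderated differential regulon testing, and
   a receptor → TF → target network with Spearman-weighted edges.
8. **Bulk integration** — TPM computation, NNLS deconvolution of bulk
   profiles against top-10-marker signatures of the HDC/DDC subclusters,
   and Spearman-correlation label transfer to treatment-group cells.

A first-class synthetic-data module generates negative-binomial UMI matrices
with two groups × four replicates, planted two-state pathway structure,
known doublets, a planted ligand → receptor → TF → target chain, and bulk
mixtures of known composition — with the ground truth saved, so every stage
is verified by recovery tests rather than by eye.

## Worked example

```python
import mitostate as ms
from mitostate.qc_preprocess import normalize_log, compute_pmem
from mitostate.pathway_scoring import gsva
from mitostate.subpopulation import (
    moderated_diff, recluster_on_scores, classify_dominance,
)
from mitostate.synthetic_data import CascadeSpec

cfg = ms.SimulationConfig(
    seed=42, cell_types=("CD-PC",), doublet_fraction=0.0,
    cascade=CascadeSpec(source_cell_type="CD-PC", target_cell_type="CD-PC"),
)
cm, catalog, pathways, lr_db, truth = ms.simulate(cfg)
pmem = compute_pmem(cm, catalog)
scores = gsva(normalize_log(cm), pathways).scores
diff = moderated_diff(scores, cm.cell_meta["group"])
clusters = recluster_on_scores(
    scores.loc[diff.significant], dims=7, resolution=0.1, seed=42,
)
assign = classify_dominance(clusters, cm.cell_meta)
```

Output for this run:

```
cells: 240, genes: 400, pathway sets: 40
mean PMEM: 8.70%
significant pathways (adj p<0.05, |dScore|>0.5): 7
clusters found: 2
         mean_frac_Ctrl  mean_frac_DKD    p call
cluster
0                0.1917         0.8333  0.0  DDC
1                0.8083         0.1667  0.0  HDC
ARI vs planted states: 0.950; per-cell state accuracy: 0.988
```

Reading it: 7 of the 40 mitochondrial pathway sets pass the dual
significance rule between Ctrl and DKD; clustering the cells on those 7
scores yields exactly two communities; cluster 0 holds 83 % of each DKD
sample's cells but only 19 % of each Ctrl sample's (t-test p < 10⁻⁴), so it
is called the disease-dominant state — and it matches the planted state for
98.8 % of cells (adjusted Rand index 0.95).

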