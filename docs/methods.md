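# Methods

## Overview

`bmecfate` implements a multi-dataset prioritization funnel for
transcription factors (TFs) able to fate pluripotent-stem-cell-derived
endothelial cells (ECs) toward brain microvascular endothelial cells
(BMECs), followed by the analysis of a pooled, barcoded
TF-overexpression single-cell screen. The funnel consumes a meta-cohort
of expression datasets of different modalities — brain single-cell
counts, murine EC microarray intensities, a zonated brain-EC dataset
with arterial/capillary/venous/large labels, and non-brain EC arrays —
together with TF regulons (a TF plus its positively regulated target
set) and a motif-ranking table. Its output is a ranked shortlist of
candidate master regulators with a complete per-TF audit trail.

## Regulon activity (ranking AUC)

Per sample, genes are ranked by decreasing expression; ties are broken
by a uniform random permutation drawn from a dedicated tie seed, because
sparse count data put large blocks of genes at zero and any fixed
tie-break would bias all zero-inflated regulons identically. A
regulon's activity is the area under the step recovery curve of its
targets within the top `auc_top_fraction` of ranks (default 0.05, the
common convention for this scoring family), normalized by the maximal
achievable area (all targets at the very top). The score lives in
[0, 1], depends only on ranks, and is therefore invariant to monotone
transforms of expression. A *reversed* context inverts each ranking so
the same statistic scores depletion; it is used to demand that candidate
regulons are inactive in non-brain ECs.

Group summaries use the interpolated 0.5 quantile (median) for
single-cell brain ECs and non-brain ECs, and the mean for the murine
array, whose brain/other-EC mean ratio defines the *relative activity*.

## Mutual information with vascular bed

The association between a regulon's per-sample AUC and the zonation
label is the plug-in mutual information of the joint contingency table
after discretizing the AUC into `ceil(N^(1/3))` equal-frequency bins,
in nats. Plug-in MI is non-negative, so the funnel's stated floor of
−1.3 can only operate on a log scale: the filter applies
`log10(MI + 1e-6) > −1.3`, i.e. it keeps regulons with MI above roughly
0.05 nats. This reading is a documented choice (the floor's original
scale is not stated) and both the transform and the floor are
configurable. A second, binary capillary-vs-other MI feeds the final
capillary filter (floor 0.05).

## Co-expression modules and motif enrichment

Signed adjacency `a_ij = ((1 + cor_ij)/2)^power` with the power chosen
as the smallest value in 1..30 whose scale-free topology fit reaches
R² ≥ 0.8 (fallback: best fit, with a warning). The topological overlap
measure TOM converts shared neighborhoods into similarity; average-
linkage clustering on `1 − TOM` gives a dendrogram that is cut at a
static height. The default cut is chosen automatically as the highest
height maximizing the number of clusters of at least `min_module_size`
(30) — the highest such cut absorbs stragglers into their module while a
cut that collapsed two modules would reduce the count and is never
selected. Clusters below the size floor form an `unassigned` pool.
Modules whose eigengene (first principal component across samples,
sign-oriented to correlate positively with module mean expression)
dissimilarity `1 − cor` is below 0.3 are merged iteratively. Gene order
is fixed (sorted) before clustering so detection is deterministic.

Module activity per sample is a single-sample rank-based enrichment
score: a weighted running sum over the descending expression ranking
(in-set genes weighted `(n − position + 1)^0.25`, out-set genes
`1/n_out`), scored as maximum positive deviation plus minimum negative
deviation, in [−1, 1]. A module covering every gene carries no ranking
information and scores 0 by construction. Scores are comparable across
samples of one dataset only — the funnel uses them for ranking, not for
cross-dataset value comparison.

Motif enrichment of a module is the normalized recovery AUC of its
genes down each TF's genome ranking (same AUC construction, top 5% of
positions), turned into an NES by z-scoring across all TFs (population
standard deviation, so the NES has exactly zero mean and unit variance
within a module). TFs with NES > 3 are flagged as candidate regulators;
the flags enter the funnel as annotations (module memberships), not as a
hard filter, because the original selection step mixed quantitative and
judgment criteria. A config switch makes them a hard filter.

## Marker sets

Differential expression is a one-vs-rest Wilcoxon rank-sum test (normal
approximation with tie correction; gates: detected in ≥ 25% of either
side and fold change ≥ 1.2 on the linear scale with pseudocount 1).
Four brain-EC marker sets are built over the universe of positive
single-cell brain-EC markers:

1. **set1** — murine brain-EC vs other-EC fold ≥ 4, and 90th-percentile
   expression in human non-brain ECs below 7× the brain-EC mean
   (pseudocount 1 on both sides);
2. **set2** — as set1 with fold ≥ 2 and percentile cap 7.5;
3. **set3** — fold ≥ 4 in brain ECs vs other brain cells in *every*
   designated single-cell dataset (intersection; union switchable);
4. **set4** — the set2 criteria plus strictly positive capillary-vs-
   large-vessel log fold change in the zonated dataset.

set1 ⊆ set2 holds by construction (4-fold ⊆ 2-fold, 7 ≤ 7.5) and is
asserted on every run. Whether the percentile cap compares against the
mean or a percentile of brain expression is an open design point; the
mean is used and configurable. Counter-marker sets (the flipped
contrasts: other-EC ≥ 2-fold, other-brain-cell ≥ 4-fold) feed the
specificity score.

## The funnel

Per TF, with every verdict and the exact threshold recorded in a
replayable `FunnelRecord`:

1. **Initial screen** — brain-EC median AUC above 0 and murine relative
   activity above 1. These floors are deliberately permissive (the
   original initial list was large and its cutoffs unstated); they are
   flagged as such in the config.
2. **Sensitivity / specificity / MI** — sensitivity(T, S) =
   |targets(T) ∩ S| / |S| must exceed 0.1 for at least one marker set
   (all-sets mode switchable); specificity(T) =
   |targets ∩ B| / |targets ∩ (B ∪ C)| (B = union of brain marker sets,
   C = union of counter sets) must exceed 0.8, undefined counting as
   fail; transformed zonation MI must exceed −1.3. The specificity
   formula is an explicit construction of a verbal definition; the
   alternative `1 − |targets ∩ C|/|C|` is available via config.
3. **Recipient expression** — TFs already expressed in the recipient
   cells (TPM ≥ 2) are dropped; a force-include list (default: ZIC3,
   retained in the original study for its known brain-EC potential)
   overrides the drop and is marked in the record.
4. **Capillary context** — capillary median AUC > 0.08 and capillary MI
   > 0.05, both strict. Survivors are ranked by descending capillary
   AUC, then best marker-set sensitivity, then count of NES-flagged
   module memberships. Module and fetal-expression criteria are soft
   annotations by default.

The funnel is monotone: relaxing any single threshold can only grow the
retained set (property-tested).

## Barcode screen analysis

**Genotype deconvolution.** A barcode is called in a cell when its UMI
count is at least `genotype_min_umis` (5) and at least
`genotype_dominance_fraction` (0.5) of the cell's top barcode count.
Genuine transduction yields tens of UMIs while ambient contamination
sits near zero, so the floor-plus-dominance rule separates
co-transduction from noise transparently; cells with more than 3 calls
are ambiguous. Calling is monotone in the UMI floor.

**Clustering.** Log-normalized counts, top 2,000 highly-variable genes
(binned variance-stabilized dispersion), scaled and clipped at ±10,
50 principal components computed and the first 15 used, k = 20 nearest
neighbors, shared-nearest-neighbor graph with Jaccard edge weights, and
seeded Leiden community detection at resolution 0.8
(RB-configuration modularity). Labels are renumbered by decreasing
cluster size. The contract is planted-population recovery (ARI ≥ 0.8 on
the synthetic screen), not label identity.

**Proportion test.** For each (cluster, genotype) pair the observed
log2 fold difference compares the genotype's share of the cluster with
all other cells' share, with a pseudocount of one cell on each
numerator. The null permutes genotype membership across cells (1,000
permutations by default; two-sided p with the +1 correction, centered at
the null mean to absorb the small pseudocount bias); the confidence
interval is an empirical bootstrap over cells. A pair is significant
when the CI lies entirely outside ±log2(1.275) *and* the permutation p
is below 0.05. The conjunction makes the test conservative: the
measured type-I rate over 200 null screens is below 0.01 at nominal
0.05, comfortably inside the ≤ 0.07 calibration bound, while a planted
3× over-representation of ~90 carrier cells among 1,500 is detected
essentially always.

## Synthetic data generator

The generator defines the verification conditions; all generators are
pure functions of (config, seed).

**Meta-cohort** (defaults: 2,000 genes, ~1,170 samples over five
datasets, 12 planted TFs vs 188 decoys — a desk-scale mirror of a
986-candidate funnel): negative-binomial counts (gamma–Poisson,
dispersion 2) with log-normal gene means for the single-cell and
zonated datasets; log-normal intensities (σ = 0.35) for the array-like
datasets. A shared brain-EC program of 120 genes carries planted murine
brain-vs-other-EC folds (60 "core" genes at 4.5–8×, 60 "secondary" at
2.2–4×), larger single-cell folds (6–12×, chosen with margin because
per-cell depth normalization compresses realized fold changes), near
silence (0.25×) in non-brain ECs, and capillary bias (log2FC 1.5–3 for
85% of the program, attenuated along arterial/venous/large beds).
Planted regulons draw ~40% of their targets from core markers and the
rest from the secondary program plus three background genes — master
regulators of one program legitimately share targets, and the sharing
keeps marker sets compact. Half the decoys carry regulons over a
100-gene non-brain EC program, half over random background. The murine
array additionally carries five 35-gene latent-factor modules
(gene–factor correlation 0.8) for module-recovery testing. Mouse
datasets use mouse-cased symbols with an explicit ortholog map.
Recipient TPMs put planted TFs below 1.5 except ZIC3 at 5 (so the
force-include path is exercised); decoys draw log-normal TPMs.

**Motif rankings**: each TF's regulon targets are pushed to the top of
its genome ranking with Gaussian noise (σ = 0.25 of the indicator
scale); zero noise places targets exactly in the top |targets| ranks.

**Barcode screen** (defaults: 1,500 cells, 1,500 genes, 12 barcodes of
20 bases, 70% transduction, 15% double-genotype rate, ambient rate
0.005, effect size 3): transduced cells receive Poisson(60) UMIs per
genotype barcode plus Poisson(ambient × 60) ambient counts elsewhere;
their target genes (30 per TF) scale by the effect size; four planted
populations carry 40-gene programs at 4×. `hit_enrichment` multiplies
the hit-cluster occupancy probability itself, so a planted "3×
enrichment" is a genuine 3× over-representation of carriers (it must
stay below the cluster count). An effect size of 1 is a biological
null: no target shift and no cluster sorting.

**What the generator does not emulate**: batch effects and platform
biases between datasets, doublet expression artifacts, ambient RNA in
the expression matrix (only in the barcode UMIs), mitochondrial content
structure, cell-cycle covariation, and realistic gene-gene correlation
beyond the planted programs and modules. Passing tests therefore show
that the pipeline recovers planted signal of realistic magnitude under
idealized independence assumptions, not that it is robust to the batch
structure of real meta-cohorts.

## Numerical choices

- Medians are interpolated 0.5 quantiles; NES and scaling use
  population (ddof 0) standard deviations.
- Equal-frequency MI binning happens on the rank scale with stable
  order, so bin occupancies differ by at most one sample.
- MAD-based cell QC treats a zero MAD as "no outliers"; mitochondrial
  fraction is filtered high-side only.
- Fold changes between group summaries use linear-scale means with
  pseudocount 1 and are reported as log2.
- Degenerate inputs fail loudly: empty gene sets, constant genes in the
  correlation network, zero-depth cells, and species mix-ups (empty
  ortholog intersection) all raise typed errors.
- Byte-level determinism of the CLI's `all` run is part of the test
  suite; every stochastic step takes an explicit seed and set iteration
  never feeds a random draw.

## Problem sizes

The default synthetic scale (2,000 genes; 320/280/150/300/120 samples;
1,500 screen cells; 200 TFs) keeps a full funnel run under ~5 s and the
entire verification suite, including ten funnel replicates and 200 null
screens, in the low minutes on one core, while leaving every planted
effect comfortably recoverable. These sizes are the package's default
study conditions, not limits of the implementation.

## Known limitations

- GSVA-style module activity is approximated by a single-sample score;
  only rank agreement across samples is contracted, not score values.
- Regulon inference itself (co-expression GRN plus motif pruning on
  real data) is out of scope: regulons and motif rankings are inputs.
- The initial-screen floors and the MI-scale reading are documented
  interpretations of under-specified steps and are exposed in config.
- The multivariate QC outlier variant and cross-dataset batch
  integration are not implemented.
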