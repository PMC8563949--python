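# Methods

`retatlas` reimplements, at desk scale and with verifiable ground truth, the
computational core of a single-cell study of primate retinal aging: a
young-vs-old cell atlas of the neural retina and RPE-choroid layers, from
UMI counts to cell-type annotation, aging differential expression,
senescence and noise scores, ligand-receptor deltas, and gene networks.
Because the original monkey dataset is not publicly available, a synthetic
STRT-seq-like generator stands in for it: every downstream claim the
pipeline makes is scored against planted truth rather than against the
study's printed numbers.

## Synthetic atlas generator (`retatlas.syndata`)

Counts are negative binomial, parameterized by mean and dispersion with
variance `mu + phi * mu^2`, sampled as a gamma-Poisson mixture. UMI-count
overdispersion is the standard assumption, and this parameterization lets
the dispersion alone carry the "transcriptional noise" effect used by the
CV analysis.

Per-(gene, cell type, age group) means start from per-gene baselines drawn
lognormally around `baseline_mean` (default 1.0 expected UMI per gene per
cell, typical of STRT-seq depth at ~1,500 genes) and are modified by the
planted effects:

| effect | default | applied to |
|---|---|---|
| `marker_log2fc` | 2.0 (x4) | 25 markers/type, own type, both ages |
| `aging_log2fc` | +-2.0, signs alternating | 20 genes/type, old cells of that type |
| `sasp_old_multiplier` | 1.5 | 30 SASP genes, old cells, all types |
| `nb_dispersion_old_multiplier` | 1.0 (off) | old-cell dispersion, `noisy_types` |
| LR activity | mean 4.0 vs 0.01 | ligand in sender, receptor in receiver, per age |
| regulator activity (optional) | lognormal sigma=1.0 | a TF and its targets, all cells |

Twenty-five markers per type at 4-fold enrichment reflects that retinal
cell classes differ in dozens of genes; it is what makes the 15 types
separable at 40 cells/type/group. Donors (8 per age group, mirroring the
8+8 animal design) multiply gene means by i.i.d. lognormal factors
(sigma=0.1), adding inter-individual variation without breaking young/old
exchangeability when all effect multipliers are 1 — that exchangeable null
underlies all calibration checks. The 15-type default uses the canonical
retinal/choroidal names with their true dissection layers (6 neural, 9
RPE-choroid); other type counts get generic names with an even layer split.

What the generator does **not** emulate: library-size gradients and
batch/plate effects beyond donor shifts, zero inflation beyond NB,
correlated gene programs (except the optional regulon), doublets, ambient
RNA, or spatial structure. Passing recovery tests here therefore shows the
statistics behave as designed under their own assumptions, not that the
original data would yield the same numbers.

## QC and normalization (`retatlas.qcnorm`)

Cells are kept when detected genes and total UMIs meet thresholds; genes
are then dropped if detected in fewer than `min_cells_per_gene` surviving
cells (gene prevalence is deliberately computed after cell removal).
Expression is `ln(count * 10^4 / cell_total + 1)`. Both the thresholds and
the scale are fixed, documented conventions — the original study states
only that filtration was "stringent" — and are echoed into the QC report
for reproducibility.

## Clustering and annotation (`retatlas.cluster_annotate`)

Highly variable genes by mean-binned standardized dispersion (20 bins,
z-scored within bin); PCA to 20 components; k-means with caller-supplied k
and seed. K-means is the contract because k is known for synthetic data and
the procedure is exactly reproducible; a graph-based clusterer can be
swapped in for real data. Markers are ranked by one-vs-rest average
difference of log expression (no test statistic), matching the "average
difference" ranking of the source analysis. Clusters are annotated to the
reference type with the highest mean marker z-score; below `min_score`
(default 0.25, on the z scale) a cluster is "unknown"; exact ties go to the
lexicographically smaller name and are logged.

## Aging differential expression (`retatlas.aging_de`)

The test statistic is the reproducibility-optimized statistic (ROTS)

    d_g = |mean_old - mean_young| / (alpha1 + alpha2 * s_g),

with `s_g` the classical pooled-variance standard error of the mean
difference. The regularization `(alpha1, alpha2)` and top-list size `k`
are chosen to maximize bootstrap top-list reproducibility standardized
against a permuted-label baseline: `Z_k = (R_k - R_k^null) / sd(R_k)`,
where `R_k` is the mean top-k overlap across pairs of within-group
bootstrap resamples. A best `Z_k < 2` flags the dataset as low-signal.
Grid defaults: alpha in {0, 0.1, ..., 1}^2 minus (0,0); k at the 1/2/5/10/20%
quantiles of the gene count; 100 bootstrap pairs.

Significance is by label permutation. When each age group contains at
least two donors, permutation is donor-stratified — the young/old split is
permuted over whole donors so cells of one donor travel together,
respecting the 8+8 animal design and avoiding pseudoreplication; otherwise
it falls back to free cell permutation with a warning. Permuted statistics
are pooled across genes (the SAM/ROTS convention), giving p-value
resolution `1/(genes x permutations)`; with only `C(16,8) = 12,870`
distinct donor splits, per-gene permutation p-values would bottom out near
2e-3 (about 1% of donor splits are >= 7/8 aligned with the truth) and
Benjamini-Hochberg would then have essentially no resolution. Because
genes with real signal retain residual effect under donor permutation and
would thicken the pooled tail, the null pool is refined by excluding
already-significant genes and recomputing, up to three passes (at least
20% of genes always remain in the pool). Under the exchangeable null the
procedure is calibrated (~5% of p-values below 0.05) and the refinement is
a no-op.

Fold changes are computed on de-logged normalized expression with
pseudocount 0.01: `log2((mean_old + 0.01)/(mean_young + 0.01))`; direction
"up" means log2fc > 0. BH runs within each cell type, since DEG counts are
reported per type. Cell types with fewer than 10 cells in either age group
are skipped and recorded.

## Scores and noise (`retatlas.scores`)

The SASP score of a cell is the plain mean normalized expression of the
SASP set — no z-scoring or control-set subtraction, exactly the "average
expression level" definition. Group comparisons use the two-sided Wilcoxon
rank-sum test on per-cell scores. The shipped SASP/GenAge/AMD/RP sets are
synthetic placeholders written by the generator; users substitute curated
lists.

Transcriptional noise is the per-gene coefficient of variation (sample SD,
ddof=1, over mean) within each (cell type, age group), restricted to genes
with mean normalized expression >= 0.1 to avoid CV blow-up at near-zero
means; strata need >= 10 cells. Old and young are compared by a paired
(across genes) Wilcoxon signed-rank test on the gene intersection. The
original study's exact CV recipe is in unavailable supplementary methods;
this definition is the package's documented choice.

## Interactions (`retatlas.interactions`)

A (sender, receiver, ligand-receptor) triple is active in an age group when
the ligand is expressed in >= 10% of the sender type's cells with group
mean >= 0.1, and the receptor passes the same thresholds in the receiver
type (a CellPhoneDB-style rule; values exactly at threshold count, with a
1e-9 epsilon absorbing float summation error). All ordered type pairs are
evaluated, including self-pairs. Young/old set algebra yields newborn
(old-only), disappeared (young-only) and unchanged classes; by
construction `|young| = unchanged + disappeared` and
`|old| = unchanged + newborn`. Multi-subunit complexes are out of scope.

## Networks (`retatlas.networks`)

Enrichment is the one-sided hypergeometric upper tail with BH correction,
against a user-supplied term->genes annotation (no GO database is bundled).
The DEG-geneset overlap network contains a gene node iff the gene is a DEG
(in the requested direction) in >= 1 cell type and belongs to >= 1 set;
node weight is the number of such cell types and edge weight the mean
signed log2 fold change over exactly those DEG-passing types (the averaging
span is this package's documented reading). The regulatory network scores
TF->target edges by |Spearman correlation| across one cell type's cells,
keeps edges >= 0.3 by default, and ranks regulators by connection count
with name tie-breaks; correlation was chosen over tree-ensemble importances
because it is deterministic and oracle-checkable, and a hook exists for
alternative scorers.

## Pipeline (`retatlas.pipeline`, `atlas` CLI)

Stages (simulate/ingest -> qc -> cluster -> deg -> scores -> interactions ->
networks) run from one YAML config and one seed; each stage derives its
sub-seed as `sha256(seed:stage) mod 2^31`, so inserting a stage cannot
silently shift the randomness of the others. Every artifact is written
under the output directory and hashed into a manifest; identical
(config, seed) reproduce the manifest byte-for-byte (logs excluded).
Stage failures abort with the stage name and a manifest marked "failed";
exit codes are 0/1/2 for ok / stage failure / config error.

## Problem sizes used in verification

The shipped benchmarks run at: 1,000 genes x 50 cells/group for DEG
calibration and recovery (200 permutations, 10 seeds for recovery); 500
cells/group x 100 seeds for the SASP shift; 2 types x 40 cells/group x 100
seeds for CV noise; the default 15-type, 1,500-gene, 1,200-cell atlas for
clustering/annotation; 600 genes x 120 cells x 100 seeds for regulator
recovery (the regulon is kept a small fraction of the transcriptome —
at much smaller universes depth normalization divides out the shared
activity factor and attenuates the planted co-expression); 500 random set
pairs / 100 random DEG tables / all hypergeometric instances with universe
<= 20 for the exact oracles. These sizes are the package's chosen
desk-scale study conditions.

## Known limitations

- The statistics are validated on NB synthetic data; real scRNA-seq
  violations (zero inflation, batch structure, ambient RNA) are untested.
- The original study's printed numbers (6,410 cells, per-type DEG counts,
  SASP medians 0.15/0.20, 1,029/766 interaction totals, per-gene fold
  changes) derive from its unreleased dataset and are not reproduction
  targets here.
- Permutation FDR control relies on donor exchangeability; with unbalanced
  or confounded donor designs the donor-stratified null is the only guard,
  and with a single donor per group the free-permutation fallback risks
  pseudoreplication (it warns).
- t-SNE/UMAP embeddings are for plots only; no quality guarantees.
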