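# Methods

This note records the models, parameter choices and numerical conventions
behind `oxistate`, and what the synthetic benchmarks do and do not
demonstrate.

## Synthetic data model

The generator is the package's ground-truth source. Single-cell counts are
negative binomial, `c ~ NB(mean μ, dispersion α)` with
`Var = μ + α μ²` and `α = 0.5` by default. Gene base means are lognormal
(log-mean −1, log-sd 1 on the natural scale), normalized per cell and scaled
to a library size drawn uniformly from 1,000–5,000 counts. On top of this:

* **Planted OS program.** A designated gene set (default 400 genes) has a
  responsive subset (200) whose means are multiplied by `2^effect_log2fc`
  (default 2-fold) in a fraction of *active* cells (default 25%). Active
  cells are placed preferentially (70%) in the early-sepsis condition. The
  boost is applied after library scaling, so the active/inactive mean ratio
  of responsive genes is exactly `2^effect_log2fc` in expectation; active
  cells carry correspondingly more total counts, which is the realistic
  direction.
* **Planted modules.** Three background gene blocks (60/60/40) each share a
  per-cell latent Gaussian factor added on the log-mean scale with loading
  0.8, producing correlation blocks recoverable by the network stage.
* **Mitochondrial genes.** The first 1% of genes carry an `MT-` prefix;
  their means are rescaled per cell so the expected mitochondrial count
  fraction equals a Beta(2, 20) draw (mean ≈ 0.09, a visible tail above the
  0.20 QC cutoff), so QC filtering is exercised end to end.
* **Bulk cohort.** Log-scale Gaussian expression (baseline N(7, 2), unit
  noise), 60 cases vs 60 controls over 300 genes of which half come from the
  OS set. Five planted hub genes (the first responsive genes) are shifted
  +1.5 SD in cases; the remaining OS genes +0.3 SD, so the cohort-level OS
  elevation seen in disease is present and the bulk OS enrichment score
  separates cases.

Defaults are the reference study conditions used throughout the tests:
2,000 cells × 2,000 genes, three conditions in equal proportion, two samples
per condition, five expression-neutral cell-type labels. Everything is a
pure function of the `SimConfig`, including its seed.

What the generator does **not** emulate: ambient RNA, doublets, batch
chemistry, realistic gene-length or GC effects, cell-type-specific
expression programs, or dropout beyond what the NB model implies. Passing
the planted-recovery benchmarks therefore shows the algorithms are
implemented correctly and are sensitive at these effect sizes — not that
they are robust to every artifact of real data.

## Scoring conventions

All five scorers operate on the log-normalized matrix and drop set genes
missing from it (with a warning).

* `auc_recovery`: recovery-curve area over the top `⌈0.05 × n_genes⌉`
  ranks, normalized by the maximal area; ties keep input order (stable
  sort), making the statistic deterministic.
* `rank_u`: decreasing-expression ranks with average ties; set ranks are
  clipped at `r_max + 1` (default `r_max` 1500) so genes lost in the
  dropout tail contribute nothing.
* `sample_rank`: mean increasing-expression rank rescaled between its
  theoretical extremes `(|s|+1)/2` and `n − (|s|−1)/2`.
* `weighted_ks`: single-sample enrichment with rank-from-top weights
  `(n − pos + 1)^0.25`; the score is the running-sum difference summed over
  all positions and divided by `n_genes`. With a single gene set the
  multi-set range normalization of the original method is undefined, so the
  `n_genes` normalizer is used instead (documented divergence).
* `binned_control`: 24 equal-occupancy mean-expression bins, 100 control
  genes per set gene sampled with replacement from the set gene's bin,
  seeded; the score is affine-covariant (not rank-invariant), unlike the
  other four.

The per-method defaults (`top_frac` 0.05, `r_max` 1500, `alpha` 0.25,
24 bins / 100 controls) are the reference defaults of the algorithms each
scorer realizes.

Consensus: per-column z-score (sample variance; the choice is immaterial
because min–max follows), min–max to [0, 1], row sum. A constant column
contributes zero with a warning rather than failing. Quartile thresholds use
linear interpolation between order statistics (quantile "type 7"), which
reproduces equal 25%-tails on distinct scores — e.g. 25,963 of 103,851 cells
on either side. Boundary ties go to the transition state because the
low/high inequalities are strict.

## Differential expression and composition

DE uses the standard single-cell marker-test recipe: per-gene two-sided
Wilcoxon rank-sum with tie and continuity correction in the normal
approximation; fold change `log2((mean(e^x − 1) + 1)_high / (… + 1)_low)`
(pseudocount 1, exponentiated scale); genes tested when detected in ≥ 10% of
either group; Bonferroni adjustment by default (`adjust="bh"` available);
strict pass filter `avg_log2FC > 0.25` and `p_adj < 0.05`.

Composition testing builds, per cell type, the 2 × 3 table (type vs rest ×
low/transition/high) and applies the chi-squared test of independence
(df = 2, no continuity correction). When any expected count is below 5 the
test switches to an exact Freeman–Halton-style test: full enumeration of
tables with the observed margins when the candidate count is ≤ 2 × 10⁵,
otherwise a seeded Monte-Carlo estimate with 10⁵ margin-preserving draws.
q-values are Benjamini–Hochberg across cell types. Null simulations (types
independent of states) put the q < 0.05 call rate at ≈ 0.015, comfortably
below the 0.07 calibration bound.

## Co-expression stage

Metacells average k-nearest-neighbor cell neighborhoods (default k = 25,
≤ 10 shared cells between accepted metacells) within each group, after a
> 5%-of-cells prevalence filter. Neighborhoods are found in a 30-component
PCA of the group's top-500 most variable genes and accepted greedily in cell
order; groups smaller than k are skipped. `build_metacells` defaults to
grouping by sample × cell type; the pipeline groups by sample alone because
the generator's cell types are expression-neutral and small sample × type
groups at desk scale leave too few acceptable neighborhoods.

The network is signed: `a = ((1 + r)/2)^β` on metacell Pearson
correlations. The scale-free fit discretizes connectivity into 10
equal-width bins and regresses log₁₀(frequency) on log₁₀(mean
connectivity); R² is sign-flipped when the slope is positive. β is the
smallest candidate with signed R² ≥ 0.9; when no candidate qualifies (the
planted-block synthetic data is deliberately not scale-free) the scan
reports the best fit with a warning, and the pipeline falls back to a
moderate default power of 6. The fallback is deliberately moderate: module
detection uses a *static* cut of the average-linkage tree on 1 − TOM
(default 0.99 of the tallest merge) instead of dynamic branch cutting, and
at high powers all TOM dissimilarities saturate toward 1, fragmenting
moderately correlated modules under any fixed cut. With the static cut the
power and the cut height trade off against each other; both are exposed in
the configuration. Clusters below 30 genes are unassigned ("grey"); modules
are named by decreasing size along the conventional color sequence.

Eigengenes are the first principal component of the standardized member
genes across metacells, unit-variance scaled and sign-oriented so the mean
correlation with members is non-negative. Module × state summaries score
each cell with the clipped rank statistic on the module's gene list and
average per state; the pipeline's candidate pool takes modules whose mean
activity peaks in the high-OS state, falling back to the passing DEGs alone
when the DEG ∩ module intersection has fewer than two genes.

## Ensemble selection

All selectors run on the bulk design restricted to the candidate genes
(standardized view for LASSO and SVM-RFE, raw for the tree methods):

* **LASSO** — L1 logistic regression over 40 log-spaced penalties, 10-fold
  stratified CV, penalty at minimum mean CV deviance (the 1-SE rule is
  available and is the sparser choice under label permutation).
* **SVM-RFE** — linear SVM, 10% of features dropped per step, feature count
  at minimum 5-fold CV error, ties resolved toward fewer features.
* **Boruta** — per-iteration shuffled shadow copies of *all* original
  features (the pool does not shrink as features are decided, keeping the
  best-shadow reference distribution constant), impurity importances from a
  500-tree forest, hits counted against the maximum shadow importance, and
  binomial confirm/reject decisions Bonferroni-adjusted across features at
  α = 0.01 over ≤ 40 iterations with a futility stop; undecided features
  are kept only if their hit record clears the unadjusted one-sided test.
  These thresholds are what make the five-way intersection empty under
  label permutation: chance-aligned noise features in a 120-sample cohort
  are real finite-sample signal, and a laxer rule admits them.
* **Random forest** — 500 trees, impurity importance, selected above the
  mean importance.
* **GBM** — depth-3 trees, learning rate 0.1, round count (≤ 100) at
  minimum 5-fold CV log-loss, selected at > 1% relative influence.

Hub genes are the exact five-way intersection, ordered by summed per-method
rank. At the reference conditions (5 genes shifted 1.5 SD among 300,
n = 120) the intersection recovers 4–5 of 5 planted genes with ≤ 1 false
positive, and is empty in ≥ 90% of label-permutation replicates.

## Bulk validation

Group differences use the same tie-corrected rank-sum test with BH
adjustment across the tested genes. AUC is computed by the rank identity
(exactly the pair-concordance definition with half-weighted ties); ROC
points are emitted per distinct threshold. The per-sample bulk OS score is
the weighted-KS enrichment of the OS set on the bulk matrix; each hub gene
is correlated with it by both Pearson and Spearman (constant genes are
flagged, not imputed).

## Determinism and problem sizes

One global seed fans out to stage-specific seeds via a CRC-folded hash, so
stages are reproducible in isolation; rerunning a pipeline configuration
reproduces every artifact byte-for-byte. The test and acceptance workloads
use the reference desk-scale conditions above (2,000-cell studies, 120-
sample cohorts, 500 composition null replicates, 5 module-recovery seeds,
10–20 permutation replicates for the selection null); these sizes make the
planted effects comfortably detectable while keeping a full run in minutes
on a single CPU.

## Known limitations

* The static tree cut is a simplification of dynamic branch cutting; module
  counts and boundaries on real data will differ, and weak modules can
  fragment at high soft powers.
* The quartile thresholds are data-dependent by construction; only the
  group *sizes* are reproducible, not the printed threshold values of any
  particular cohort.
* The exact composition test enumerates or samples 2 × 3 tables only; wider
  state spaces would need a generalized implementation.
* Boruta here differs from the R reference in its fixed shadow pool,
  impurity importances and iteration budget (see above for why); on small
  cohorts these choices are the conservative ones.
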