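# oxistate

Consensus scoring of oxidative-stress (OS) activity in single-cell
transcriptomes, quartile partitioning of cells into OS states, and
downstream discovery and validation of OS-associated hub genes.

## The problem

In sepsis, oxidative stress spikes early and unevenly across immune cell
populations. Given (a) a single-cell count matrix from control and sepsis
samples, (b) a curated list of OS-related genes, and (c) a labeled bulk
case/control cohort, the package answers: which cells are in a high-OS
state, which genes move with that state, which co-expression modules carry
the program, and which of those genes hold up as diagnostic biomarkers in
bulk cohorts?

## The method

1. **QC and normalization** — cells kept with mitochondrial fraction
   < 20% and detected genes in (200, 7000]; genes kept when detected in ≥ 3
   cells; log-normalization `ln(1 + c/total × 10⁴)`; top-3000 HVGs by binned
   standardized dispersion.
2. **Five-algorithm OS scoring** — each cell is scored for the OS gene set
   by five independent statistics: the recovery-curve AUC of set genes in
   the top of the expression ranking, a clipped Mann–Whitney *U* rank score,
   a rescaled mean-rank score, a weighted Kolmogorov–Smirnov running-sum
   enrichment, and an expression-bin-matched control score.
3. **Consensus and states** — each score column is z-scored, min–max scaled
   to [0, 1], and row-summed into a composite ∈ [0, 5]; cells below the 25th
   percentile are the **low**-OS state, above the 75th the **high**-OS
   state, the rest **transition**.
4. **State analysis** — Wilcoxon rank-sum differential expression between
   high and low states with the strict filter `avg_log2FC > 0.25` and
   `p_adj < 0.05`, plus per-cell-type chi-squared (or exact) tests of state
   composition with FDR correction.
5. **Co-expression modules** — genes expressed in > 5% of cells are
   aggregated into k-NN metacells per group; a signed weighted network
   `a = ((1+r)/2)^β` with β chosen by scale-free fit ≥ 0.9; topological
   overlap, average-linkage clustering, static cut, module eigengenes, and
   module × state activity summaries.
6. **Hub genes** — candidate genes (DEGs ∩ high-state modules) are screened
   on the bulk cohort by LASSO, SVM-RFE, Boruta, random forest, and GBM; the
   hub genes are the strict five-way intersection.
7. **Bulk validation** — rank-sum group differences, ROC/AUC, and
   correlation of each hub gene with the bulk OS enrichment score.

A seeded synthetic-data generator (negative-binomial counts, planted OS
program, planted gene modules, planted bulk hub genes) makes every stage
testable without external downloads.

## Worked example

```python
from oxistate import SimConfig, simulate_study, qc_filter, log_normalize, score_cells

cells, bulk, os_set, truth = simulate_study(SimConfig(seed=1))
cells = log_normalize(qc_filter(cells))
panel = score_cells(cells, os_set, seed=0)
print(f"q1={panel.q1:.3f} q3={panel.q3:.3f}")
print(panel.state.value_counts().to_dict())
```

prints

```
q1=1.472 q3=2.558
{'transition': 938, 'low': 470, 'high': 470}
```

i.e. of the 1,878 QC-passing cells, the quartile rule labels 470 low-OS and
470 high-OS, with composite-score thresholds 1.472 and 2.558 on the [0, 5]
consensus scale. Comparing the high calls with the planted truth at these
study conditions gives precision/recall ≈ 0.95.

The same analysis runs end-to-end from a YAML config:

```bash
oxistate run --config run.yaml     # stages: simulate/load → qc → score →
                                   # states → deg → composition → coexpr →
                                   # select → validate-bulk → report
```

with `run.yaml` as small as:

```yaml
out_dir: out/
seed: 1
simulate: {}
```

Individual stages are also exposed (`oxistate simulate|qc|score|states|deg|
composition|coexpr|select|validate-bulk`).

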