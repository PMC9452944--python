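# ataxic

Per-cell scoring of **transcriptomic-perturbation heterogeneity** in
single-cell RNA-seq data, for researchers studying intratumor heterogeneity
from scRNA-seq cohorts of cancer cells.

Most single-cell heterogeneity measures ask *how far* a cell's transcriptome
deviates from the population. This score instead asks *how unevenly* it
deviates: a cell whose genes all shift by comparable standardized amounts is
"synchronously" perturbed, while a cell in which some genes are wildly
perturbed and others are quiet is "asynchronously" perturbed. Asynchronous
perturbation tracks proliferation and oncogenic signature activity, aggressive
phenotypes, and drug resistance.

## The score

Given a normalized (log2(TPM+1)) expression matrix with *m* genes and *t*
cells, each gene *i* is standardized across cells:

```
z_ic = (x_ic − mean_c(x_i)) / sd_c(x_i)        (sample SD, denominator t−1)
```

Genes with zero variance have no defined z-score and are dropped (and
reported). The score of cell *c* is the sample standard deviation, over the
*m′* retained genes, of the absolute z-scores:

```
score(c) = sd_i( |z_ic| )                       (denominator m′−1)
```

The score is non-negative, invariant under any per-gene affine rescaling of
the input, and identically zero when *t* = 2. Scoring can be **scoped**: the
per-gene means and SDs can be computed within each sample (patient)
independently (default) or once across a whole cohort.

Around the score the package provides:

* **Quality control** in the conventional order for TPM-scale scRNA-seq data:
  remove cells expressing fewer than 300 genes, cells with more than 10%
  mitochondrial expression, and samples with fewer than 10 cells; then
  log2(TPM+1) transform. All thresholds are strict inequalities.
* **Signature enrichment**: the mean expression of a gene set's members in
  each cell (GMT input).
* **Association statistics**: Spearman correlation (average ranks, exact
  permutation p for n ≤ 9), Benjamini–Hochberg FDR, one-tailed Mann–Whitney U
  (exact when feasible), Shapiro–Wilk annotation, and a compound-viability
  correlation screen across cell lines.
* **A synthetic cohort generator** with per-cell ground-truth asynchrony, so
  the whole pipeline is testable without any download.

## Worked example

The score of a 3-gene × 3-cell toy matrix (G1 = (1,2,3), G2 = (2,2,2),
G3 = (0,1,5)) can be checked by hand: G1's z-scores are (−1, 0, 1), G3's are
(−2, −1, 3)/√7, and G2 is constant so it is dropped. Each cell's score is then
the SD of its two absolute z-scores, `| |z_G1| − |z_G3| | / √2`:

```python
import numpy as np
from ataxic import ExpressionMatrix, ataxic_scores

mat = ExpressionMatrix(
    gene_ids=["G1", "G2", "G3"],
    cell_ids=["c1", "c2", "c3"],
    values=np.array([[1, 2, 3], [2, 2, 2], [0, 1, 5]], dtype=float),
    sample_of_cell={"c1": "P1", "c2": "P1", "c3": "P1"},
    norm_state="log2p1",
)
res = ataxic_scores(mat, scope="cohort")
print(res.table.frame)
print("dropped:", res.dropped_genes)
```

prints

```
  cell_id sample_id     score
0      c1        P1  0.172584
1      c2        P1  0.267261
2      c3        P1  0.094677
dropped: {'cohort': ['G2']}
```

Cell c2 sits exactly at the population mean of G1 (|z| = 0) while deviating
moderately on G3 — the most *uneven* deviation profile of the three cells, so
it scores highest.

On simulated data the score recovers the planted per-cell asynchrony:

```python
from ataxic import SimConfig, recovery_experiment

cfg = SimConfig(seed=1, n_genes=2000, n_cells_per_sample=(300,),
                perturbation_scale=2.0)
report = recovery_experiment(cfg, n_reps=10)
print(f"mean rho = {report.mean_rho:.3f} (SD {report.sd_rho:.3f}) "
      f"over {report.n_reps} replicates")
```

prints

```
mean rho = 0.909 (SD 0.015) over 10 replicates
```

i.e. the Spearman correlation between each cell's true asynchrony level and
its computed score averages 0.909 across ten independently simulated
2000-gene × 300-cell cohorts.

## Command line

The `ataxic` console script wires the same operations into subcommands:

```sh
ataxic simulate outdir --seed 1                      # synthetic cohort + truth
ataxic qc outdir/matrix.tsv --labels outdir/labels.tsv \
       --out-matrix qc.tsv --out-report qc_report.tsv
ataxic score qc.tsv --labels outdir/labels.tsv --out scores.tsv
ataxic enrich qc.tsv --gmt outdir/signatures.gmt --out enrichment.tsv
ataxic correlate scores.tsv sig_column.tsv --out correlations.tsv
ataxic run config.yaml                               # full pipeline from YAML
```

Outputs are TSV; logs go to stderr; a full `run` writes a provenance file
(tool version, config hash, seed) and is byte-reproducible for a fixed
config.

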