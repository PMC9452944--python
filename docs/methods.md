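# Methods

## The heterogeneity score

For a normalized genes × cells matrix (log2(TPM+1)), every gene is z-scored
across the cells in the scoring scope (mean subtracted, divided by the sample
standard deviation with denominator t−1). A cell's score is the sample
standard deviation, across the m′ retained genes (denominator m′−1), of the
absolute values of its z-scores.

The absolute value is essential: the score measures how *unequal* the
standardized deviation magnitudes are across a cell's genes, not their
direction or overall size. Consequences that the tests assert directly:

* **Per-gene affine invariance.** Replacing a gene row x_i by a_i·x_i + b_i
  (a_i ≠ 0) flips or rescales z_i but leaves |z_i| unchanged, so no score
  moves. A measurement that uniformly shifts or rescales genes cannot change
  the score.
* **Two-cell degeneracy.** With t = 2 and untied values every |z| equals
  1/√2, so all scores are exactly 0. Scores become informative only as the
  cell population grows.
* **Zero floor.** A cell whose expression equals every gene's cross-cell
  mean has all z = 0 and scores 0; more generally score = 0 iff all |z| of
  the cell coincide.

Zero-variance genes have no defined z-score. They are dropped before scoring
and reported per scope group, never imputed as z = 0, which would dilute the
|z| population with artificial zeros.

### Scoring scope

Per-gene means and SDs can be computed within each sample (patient)
independently (`scope="sample"`, the default, appropriate for per-patient
correlation analyses) or once over the whole matrix (`scope="cohort"`,
appropriate for cross-sample comparisons and cell-line panels). Which choice
matches a given published analysis is generally not knowable from the
analysis description alone, so both are explicit and neither is guessed
silently: per-sample runs require every sample to have ≥ 2 cells and ≥ 2
retained genes, and errors name the offending group.

## Quality control

Defaults, applied in order on the raw TPM-like matrix:

| filter | default | meaning |
| --- | --- | --- |
| low-complexity cells | min_genes = 300 | cells expressing (value > 0) fewer than 300 genes are removed |
| high-mito cells | max_frac = 0.10 | cells whose mitochondrial share of total expression exceeds 10% are removed |
| small samples | min_cells = 10 | samples contributing fewer than 10 cells (after the cell filters) are dropped entirely |
| normalization | log2(v+1) | applied last; the matrix records its state |

All thresholds are strict inequalities: exactly 300 expressed genes, exactly
10% mitochondrial content, and exactly 10 cells are retained. "Expressed"
means strictly positive, since in a TPM matrix zero means undetected. The
mitochondrial fraction is computed on the raw linear scale, where a
percentage of total expression is meaningful; mitochondrial genes are
identified by a case-insensitive `MT-` prefix on gene symbols by default,
overridable as a regular expression, since annotation conventions vary.
The sample-size filter runs after the cell filters deliberately: a sample is
judged on the cells that survive QC, so a 10-cell sample losing one
low-quality cell is excluded. Cells with zero total expression are removed
under a distinct reason code (their mitochondrial fraction is undefined).
The QC report records, in order, every step with counts and dimensions, and
the per-cell removal counts always sum to input − output cells.

## Signature enrichment

The enrichment score of a gene set in a cell is the arithmetic mean of the
cell's expression over the set's genes present in the matrix. Rank-based
alternatives (ssGSEA/AUCell-style) are deliberately out of scope; the plain
mean keeps enrichment linear in expression, which the tests assert. Gene
matching is exact and case-sensitive by default with an explicit
case-insensitive fallback; missing genes are excluded from the mean (not
zero-imputed) and reported.

## Statistics

* **Spearman correlation** uses average ranks for ties. For n ≤ 9 the
  two-sided p-value is computed by full enumeration of the n! permutations of
  one ranking (valid under ties, since the enumeration conditions on the
  observed values); for larger n the t approximation on n−2 degrees of
  freedom is used. Constant vectors raise an error at the function level and
  become flagged records in tables — rho is undefined there, and a flagged
  record is honest where a number would not be.
* **BH adjustment** is the standard step-up procedure (delegated to
  statsmodels, cross-checked in tests against the min-over-tail definition).
  The default correction pool is one analysis call — e.g. one covariate
  across all patient groups — matching the way per-figure analyses are
  usually framed; callers wanting a wider pool can adjust pooled p-values
  themselves. Flagged records are excluded from the pool.
* **Mann–Whitney U** is one-tailed with a caller-supplied direction (the
  direction of a hypothesis is a scientific choice, never inferred from the
  data). The p-value is exact by enumeration when n_a·n_b ≤ 100 and there are
  no ties — a threshold chosen for test determinism — otherwise the
  tie-corrected normal approximation is used, and the record says which.
* **Shapiro–Wilk** (3 ≤ n ≤ 5000) annotates reports only; it never switches
  methods silently. Group comparisons are rank-based regardless, because
  score distributions are typically non-Gaussian.
* **Compound screen**: per compound, Spearman between per-line scores and
  viability with pairwise deletion of missing values, requiring ≥ 3 usable
  lines; BH across all tested compounds; significant correlations counted by
  sign at the FDR threshold (default 0.05). Positive means higher scores
  accompany higher viability under treatment, i.e. resistance.

## The synthetic cohort generator

The generator emulates the input the scorer is designed for: a multi-patient
TPM-like scRNA-seq matrix in which each cell has a known degree of
perturbation asynchrony.

Model, all on the log2 scale until the final exponentiation:

1. per-gene baseline ~ Normal(3, 2) (log2 units; spans the several orders of
   magnitude typical of TPM);
2. per-cell Gaussian noise on every gene, SD 0.3;
3. for a cell with asynchrony a ∈ [0,1], a random subset of
   `perturbed_gene_fraction · a · n_genes` genes (fraction default 0.2)
   receives additive Laplace(0, `perturbation_scale`) perturbations. The
   perturbation is sparse and heavy-tailed *by design*: a uniform shift of
   all genes is exactly what the score is blind to (affine invariance), so
   the planted signal must widen the dispersion of |z|, not move its mean;
4. signature modules are disjoint gene blocks whose mean expression is
   coupled to a (±1 log2 unit per unit of a by default, or uncoupled),
   giving correlation analyses a known answer;
5. designated high-mito cells get their `MT-` genes rescaled to a
   mitochondrial fraction drawn from (0.15, 0.5); designated low-quality
   cells keep only 150 expressed genes (below the 300-gene QC threshold);
6. values are exponentiated and each cell rescaled to a fixed column sum of
   10⁶, so the log2(TPM+1) path is exercised realistically.

A single mandatory seed drives everything; the same config is bit-for-bit
reproducible. The generator's coupling contract — cells with higher true
asynchrony have higher scores on average — is itself tested, as is the
recovery experiment: at 2000 genes × 300 cells with uniform asynchrony and
perturbation scale 2, the mean Spearman correlation between truth and score
exceeds 0.8 over ten replicates, while with perturbation scale 0 the mean
absolute correlation stays below 0.1 over twenty.

What the generator does **not** emulate: UMI/count noise and dropout beyond
the simple zeroing of low-quality cells, batch effects, doublets, ambient
RNA, or realistic gene–gene correlation structure. Passing tests on this
generator therefore show that the implementation computes the intended
statistic and that the statistic detects the kind of signal it claims to
detect — not that the score is robust to every artifact of real scRNA-seq
chemistry.

## Numerical and design choices

* Both standard deviations use the sample (n−1) denominator.
* The in-memory container is a small validated dataclass rather than an
  AnnData object: the toolkit needs a normalization-state flag with
  state-checked transitions and strict label invariants, and no neighborhood
  of scanpy functionality; matrices are dense (cohorts of this scale fit
  comfortably in memory, and the score is a dense computation anyway).
* Dense matrices are written with 17 significant digits so every
  reader/writer pair round-trips values to 1e−12 and identifiers exactly;
  readers never reorder genes or cells.
* Dense-matrix orientation is an explicit flag (default genes-in-rows);
  MatrixMarket indices are 1-based per the standard; cells missing from an
  explicit label table are rejected, not defaulted.
* Pipeline outputs contain no timestamps, so a rerun of the same YAML config
  is byte-identical; provenance (tool version, config hash, seed) is written
  alongside the result tables.
* Problem sizes in the test suite and acceptance script (up to 2000 genes ×
  300 cells, tens of replicates, a 300-compound × 120-line screen) are chosen
  so the full validation cycle completes in well under a minute while keeping
  every group large enough for the asymptotic statistics to behave.

## Known limitations

* The score conflates technical and biological dispersion: any artifact that
  inflates a cell's |z| spread (e.g. library-size effects surviving
  normalization) inflates the score.
* Per-sample scoping makes scores incomparable across samples with very
  different cell counts; the cohort scope makes them comparable but lets
  large samples dominate the per-gene statistics.
* The exact Spearman p is enumeration-limited to n ≤ 9; beyond that the t
  approximation is used even in the presence of heavy ties.
* The screen assumes viability rows are independent compounds; correlated
  compound families make the BH correction conservative in expectation but
  not guaranteed FDR control.
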