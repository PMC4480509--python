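# scvarcal

Technical-noise calibration and expression-variability analysis for deep
single-cell RNA sequencing.

Single-cell transcriptomes vary between cells of the same type — but so
do repeated measurements of the same RNA. With roughly 300,000 mRNA
molecules and ~10,000 expressed genes per cell, the average gene is
represented by ~30 molecules, and at those copy numbers capture and
amplification noise can masquerade as biology. `scvarcal` is for analysts
who sequence **dilution controls** alongside their cells — bulk RNA
diluted to single-cell mass (10/50/100 pg), amplified and sequenced like
a cell — and want to use them to decide which genes are quantified
reliably and which genes vary more than the measurement does.

## What it computes

Let x_i be gene i's mean relative frequency (count / library total). From
the dilution replicates the package builds a **control curve** V_exp(x):
the per-gene variance across replicates, summarised at each expression
level by the median over 500 neighbouring genes. Everything else hangs
off that curve:

- **Reliability thresholds** — the expression level above which (1) genes
  have no missing values in the controls, (2) cell-to-cell variance
  exceeds 2 x V_exp, and (3) control noise is approximately normal
  (windowed median Shapiro–Wilk p > 0.01); the selected threshold is the
  most stringent of the three, convertible to input molecules
  (e.g. 6.3e-5 x 150,000 ≈ 9 molecules).
- **The expression-matched F-statistic** for each gene in a cell type:

      F_i = V_total(g_i, x_i) / V_exp(x_i)

  total variance across that type's cells over control variance at
  matched expression. F ≈ 1 means the gene varies like the measurement;
  the top 5 % by F are the cell type's variable genes.
- **Pattern classification** — the outlier-sum statistic (median/MAD
  standardisation, upper Tukey fence) for genes high in a minority of
  cells; Shapiro–Wilk consistency; divergent genes (variable in one cell
  type, normally distributed in another); and the association of
  variability with short RNA half-life.
- **Cross-species conservation** — the partial correlation of log10 F
  between species given both species' expression levels, over one-to-one
  homologues.
- **Common-gene machinery** — universal genes, per-type top-400 common
  genes by minimum count, Jaccard overlap with a matched-size permutation
  test, and a generic enrichment engine over user-supplied annotations.
- **3' UTR termination sites** — candidate ends called per cell from the
  smoothed antisense-minus-sense read-start differential (paired-end
  chemistry leaves unmatched antisense starts only at true 3' termini),
  scored across cells with a 200-bp match rule and classified as
  consistent, variable, or cell-type-specific usage.
- **A synthetic-data generator** that emulates the full study design (91
  cells over five cell types, 12+9+9 dilution replicates, binomial
  capture → log-normal amplification → multinomial sequencing, planted
  hypervariable genes and 3' ends) with ground truth emitted beside every
  matrix — the package's own test bed.

Counts travel as plain TSV/MatrixMarket; tracks as 6-column BED. See
`docs/methods.md` for the model and every numerical choice, and
`examples/` for one short runnable script per capability.

## A worked example

`examples/02_reliability_threshold.py` simulates 12 dilution replicates
at 10 pg plus 91 cells, builds the control curve and evaluates the
criteria:

```
control curve: 3000 genes, window 301; V_exp spans 0.00e+00 .. 1.10e-04
criterion 1 (completeness)   : 4.90e-05
criterion 2 (2x variance)    : 3.56e-06
criterion 3 (normality)      : 1.28e-05
criterion 4 (breakpoint, diagnostic only): 5.68e-05
selected (max of 1-3)        : 4.90e-05
equivalent input molecules at 150,000 per cell: 7.35 (~7)
```

The three criteria land within a factor of a few of each other, and the
selected relative-frequency threshold of ~5e-5 says quantification is
reliable from roughly seven input molecules upward — genes below it are
excluded from variability analysis. `examples/03_variable_genes.py` then
ranks genes by F against that curve:

```
1076 genes above the reliability threshold (5.45e-05 relative frequency)
median F = 1.25 (bulk of the transcriptome is near the technical floor)
F > 10 for 25 genes (candidate biologically variable genes)
top 5% = 54 genes; recall of planted hypervariable set: 0.86
```

A median F near 1 shows the calibration is honest; the planted
hypervariable genes (tenfold variance inflation) surface in the top 5 %.

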