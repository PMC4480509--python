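# Methods

`scvarcal` separates technical from biological variation in deep
single-cell RNA-seq using dilution controls: bulk RNA diluted to
single-cell mass (10/50/100 pg), amplified and sequenced exactly like a
cell. Everything downstream — the reliability thresholds, the
expression-matched F-statistic, the pattern classifiers — is calibrated
against those controls. This note records the model, the numerical
choices, and what the synthetic data do and do not establish.

## Synthetic data: the generative model

Every simulated library follows one chain:

    molecules -> Binomial capture -> log-normal amplification
              -> Multinomial sequencing at fixed depth

This is the simplest chain that reproduces the two facts the calibration
depends on: technical noise grows as expression and input amount fall
(capture is binomial, so relative noise scales as 1/sqrt(molecules)), and
genes below a few tens of molecules drop out. It makes no attempt to model
amplification-cycle correlations, GC or length bias (correlations of
those traits with counts are negligible in this assay class), positional
coverage bias, or doublets.

Defaults (all exposed on `SyntheticSpec`):

| parameter | default | meaning |
|---|---|---|
| `cell_type_sizes` | 13/19/19/18/22 | five cell types, 91 cells |
| `dilution_design` | (10 pg, 12), (50 pg, 9), (100 pg, 9) | control replicates |
| `molecules_per_10pg` | 150,000 | molecule pool per 10 pg; 50/100 pg scale linearly |
| `mean_expression_model` | log-normal(ln 30, 2.0) | wide abundance distribution; ~30 molecules/gene at 5,000 genes |
| `capture_efficiency` | 0.3 | binomial capture probability per molecule |
| `amplification_noise_sd` | 0.25 | log-normal sd, ~25 % CV at high expression |
| `target_depth` | 500,000 | reads per sample (desk scale; the assay itself is deeper) |
| `background_dispersion_sd` | 0.15 | biological log-normal sd of unplanted genes |
| `planted_hypervariable` | (0.05, 16, 0.5) | fraction, on-state fold change, on-probability |
| `planted_cross_species_rho` | 0.5 | correlation of per-gene excess dispersions |

The bulk molecule profile is integerised by largest remainder so that the
noise-free limit (capture 1, amplification sd 0) reproduces the profile
*exactly* at the pre-sequencing stage. Per-cell expression is renormalised
to the fixed molecule pool, modelling constant cellular mRNA content;
planted on/off genes therefore perturb other genes compositionally, as
they would in a real library. Hypervariable genes are planted either as
two-state mixtures (off mean vs on mean x fold change) or, in
`"inflation"` mode, with a per-gene log-normal whose variance is
calibrated to `(variance_inflation - 1)` times the analytic technical
CV^2 at that gene's abundance — the mode used for recovery benchmarks,
since it pins the target F-statistic (≈ 10 at the default inflation)
uniformly across expression levels.

Ground truth (planted flags, true biological CV^2, per-gene dispersions)
is emitted alongside every matrix; tests never re-derive it from realized
data. All randomness derives from one integer seed through named
`SeedSequence` streams, so identical spec + seed reproduce every output
byte for byte.

What passing tests on these data show: the estimators are calibrated and
recover planted structure under the stated noise model. What they do not
show: robustness to amplification chemistry artefacts, batch structure,
ambient RNA, or cell types whose total mRNA content differs — on real
data those enter the F-statistic as unmodelled technical variance.

## Normalization and QC

Size factors are median-of-ratios: the pseudo-reference is the per-gene
geometric mean (computed in log space) over the genes detected in every
sample; each sample's factor is the median ratio to that reference, with
the arithmetic midpoint for even-sized reference sets. Samples need one
ubiquitously expressed gene or normalization refuses with an explicit
error. Sample QC keeps a library only if its unique exonic reads exceed
5 million and it passes at least 2 of 3 traits (>= 50 % unique mapping,
>= 1,500 genes with more than 10 reads, < 80 % short fragments); a trait
whose statistic is unavailable lowers the requirement by one, so samples
lacking the short-fragment statistic need 1 of the 2 remaining. PCA runs
on arcsin(sqrt(relative frequency)) with genes centred and unscaled
(centring is the conventional default; the choice is exposed). Saturation
curves subsample reads *without* replacement (multivariate
hypergeometric), matching the definition of subsampling a fixed library.

## Control curve and reliability criteria

The control curve is the per-gene sample variance (ddof = 1) of relative
frequencies across the 10 pg dilution replicates, genes sorted by mean
relative frequency (ties broken by gene id), smoothed by a sliding median
over 500 neighbouring genes. At the curve's edges the window truncates
symmetrically; lookup is nearest-x, piecewise constant — the curve is a
kernel median, not a parametric fit, so no interpolation is invented.

The four criteria and their numerics:

1. **Completeness** — windowed fraction of genes with no zero count in any
   replicate; threshold is the lowest level above which that fraction
   stays >= 0.5.
2. **Biological excess** — windowed median of the per-gene ratio
   (single-cell variance / control variance at that gene's level) must
   exceed 2. The ratio is formed per gene *before* the median so both
   sides sit at the same expression level; comparing a windowed median of
   variances against a lookup at the window-centre gene misaligns the two
   by half a window and collapses at the top of the range. "Single cells"
   means all cells pooled across types, so between-type differences
   contribute — with technical-only cells this criterion is correctly
   unattainable and is reported as +inf.
3. **Normality** — windowed median Shapiro–Wilk p (computed per gene on
   the raw dilution relative frequencies) must exceed 0.01 at every higher
   level. A constant gene gets p = 0 (degenerate, not normal).
4. **Depth–rank breakpoint** — the split minimising the two-segment
   least-squares error of log depth vs log rank. Reported as a diagnostic
   only and excluded from selection: no operational decision rule exists
   for "consistent functional relationship", and inventing one would be
   arbitrary.

For criteria 1–3 the windows keep full width at the edges of the
expression range (slid inward rather than shrunk): with shrinking windows
the top-of-range "median" degenerates to a single gene's p-value and the
"for all higher levels" rule fires on individual-gene noise. The curve
itself keeps symmetric truncation; only the criterion scans differ.

The selected threshold is the maximum of criteria 1–3 and raises an
explicit error if any is +inf; `select(criteria=(1, 3))` supports
dilution-side-only selection, which is what a technical-only calibration
run needs. Conversions report threshold x 150,000 molecules and
threshold x library size, raw and rounded.

## F-statistic and downstream analyses

F_i = V_total(i) / V_exp(x_i), both sides unbiased (n-1) sample variances
on relative frequencies, the denominator read off the control curve at
the gene's mean expression. Under a pure technical model the median F
sits near 1.03, not exactly 1: the denominator is a median of ~chi^2_11
variance estimates (median < mean), the numerator ~chi^2_19. That ~3 %
bias is inherent to the median-kernel design and well inside the
calibration band. Top-variable selection takes ceil(fraction x n) genes
by F, ties broken by larger mean expression then gene id.

The functional-category ANCOVA fits log10 F ~ category + cell type +
log10 mean normalized depth by OLS (statsmodels); genes in multiple
categories are excluded as ambiguous factor levels. Adjusted means are
evaluated at the grand-mean covariate, averaging cell-type effects with
equal weights. Simultaneous pairwise intervals and family-wise p-values
come from the max-|t| statistic of the joint t distribution of the
contrast estimates, computed by Monte Carlo (20,000 draws from the exact
multivariate t with the contrasts' correlation, fixed internal seed, so
inference is deterministic).

Cross-species conservation: per species, log10 F is regressed on an
intercept and the log10 mean expression of *both* species; rho is the
Pearson correlation of the residual vectors with a two-sided t test on
n - 4 degrees of freedom. Only homologues passing the threshold in both
species enter; ambiguous (non-one-to-one) homologue rows are an error,
with `filter_one_to_one_homologues` as the explicit pre-step. Recovery
benchmarks run the estimator on the generator's ground-truth variability
tables: with 8 cells per type the sampling noise of F itself attenuates
any correlation far below its true value, so only the ground-truth route
isolates the confound-removal machinery (the count route is exercised
qualitatively in the unit tests).

Within/between cell-type variances are computed on arcsine-transformed
relative frequencies; the between-pair value is the mean per-gene
variance across all cells of both types pooled. The pooled decomposition
is a declared choice (several decompositions fit the words "variance
between each pair"); it is stated in the output rather than hidden.

## Expression-pattern classification

The outlier sum standardises by the median and the *unscaled* median
absolute deviation (no 1.4826 consistency factor; an option restores it),
falling back to the smallest non-zero value in the transcriptome when the
MAD is zero so single-outlier genes are not lost. Outliers are
standardized values strictly above the upper Tukey fence q75(z) + IQR(z),
upper tail only (the statistic targets high expression in a sample
subset; a two-sided option exists). Values are normalized read counts by
default. One structural property worth knowing: the fence is computed
from the full sample, so once the high state exceeds about a quarter of
the cells the fence rises above it and OS drops to zero — the statistic
is a minority-subset detector by construction, and the test suite pins
this behaviour down explicitly.

Variable = top 400 by OS within a cell type and OS >= 100; consistent =
top 400 by Shapiro–Wilk W and p > 0.005, never simultaneously variable;
divergent = variable in >= 1 type and consistent in >= 1 other. The
half-life association ranks genes by half-life (ties broken by gene id),
takes the bottom third as fast-decaying and the top third as slow,
drops the middle, excludes genes flagged both ways, and runs a plain
chi-square (no continuity correction, so the statistic equals the
textbook formula) on the 2x2 table.

## Common genes and overlap testing

Universal genes have >= 1 read in every sample. Per-type common genes
rank non-universal genes by descending minimum raw count across the
type's cells (raw counts; a switch allows normalized), ties by descending
mean then gene id. The Jaccard permutation test draws matched-size lists
from each universe and counts permuted J >= observed; zero exceedances
report p = 1/n_perm flagged as an upper bound, keeping p in (0, 1]. The
enrichment engine is a per-term 2x2 with an upper-tail hypergeometric (or
chi-square) test, Bonferroni-corrected across tested terms, with the
enrichment ratio defined as the annotated fraction in the query over the
annotated fraction in the remaining background.

## 3' UTR end detection

Paired-end chemistry produces matched sense/antisense read-start pairs
around internal fragmentation points; only a transcript's 3' terminus
accumulates antisense starts with no sense partners. The caller smooths
per-position read-start multiplicities with a 50-base window stepped by
5, forms the antisense-minus-sense differential, and calls candidates at
positive local maxima that (a) reach the 98th percentile of window
heights *within the gene's analysis window* (per-gene percentile
normalization; a genome-wide variant is a flag) and (b) carry a read
depth of >= 10 antisense starts *in excess of* sense starts in the apex
window. The excess reading of the depth gate follows from the chemistry:
matched pairs feed both strands equally and carry no end evidence, and a
raw-count gate would admit every well-covered null gene, making the null
calibration (no candidates on fragmentation-only tracks) impossible.
Plateau apexes resolve to the most-3' window — the termination side.
The analysis window is 1,000 bp either side of the annotated end;
single-exon-gene restriction is an input-filter flag, default on.

Cross-cell coherence uses the 200-bp match rule throughout: candidate
ends are clustered across cells by greedy single-linkage within 200 bp
(cluster representative = median), and a cell "has" a reference peak if
one of its candidates lies within 200 bp of it. Cell types with fewer
than 5 expressing cells are ignored per gene. Classes: consistent (every
end >= 0.8 in every retained type, >= 2 types), variable (every end
< 0.6 everywhere), cell-type-specific (some end >= 0.8 in one type and
below 0.8 or absent in another, not consistent), otherwise unclassified.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so the statistical checks keep their power: 5,000 genes / 20 cells
for the F-null calibration; 100 replicates of 2,000 genes for
hypervariable recovery; 100 seeded runs (50 in the script) of 1,500 genes
x 3 input amounts for threshold ordering; 5,000 homologues for the
cross-species recovery; 200 (100 in the script) genes per class plus as
many nulls for the UTR round trip; 500-gene lists from 5,000-gene
universes for the Jaccard null calibration, where the sizes are what make
the discrete null J distribution near-continuous enough for a
Kolmogorov–Smirnov uniformity check. Every stochastic routine takes an
explicit seed and derives sub-stream seeds below 2^31.

## Known limitations

- The generative chain is one admissible technical-noise model; the assay
  itself is characterised only as approximately normal above threshold,
  so alternative chains with the same first two moments would calibrate
  identically.
- The F-statistic carries the ~3 % median-kernel bias noted above and is
  confounded by total-RNA differences between cell types; like the
  procedure it implements, it supports within-cell-type comparisons, not
  absolute cross-type statements.
- The ANCOVA's family-wise correction is Monte-Carlo (20k draws); p-values
  below ~1e-4 are reported at that resolution.
- The UTR caller assumes 3'-biased, strand-faithful libraries; chemistry
  producing unpaired strand artefacts at rates far above the modelled
  orphan rate would need the depth gate re-examined.
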