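# Methods

`pairdmr` implements the statistical machinery for detecting persistent
differential DNA methylation after an early-gestational exposure in a
paired same-sex sibling design, from per-CpG bisulfite read counts through
region- and pathway-level testing to replication bounds and phenotype
association. This note documents the models, the numerical choices and the
limits of what the synthetic-data tests demonstrate.

## Study design and data model

The unit of design is the sibling pair: one member exposed around
conception (timed by the mother's last menstrual period, LMP), the other
conceived before or after the exposure window, always of the same sex.
Pairing removes family background and most genetic variation from the
exposure contrast, so all inference is within-pair.

Input data are BED-dialect tables of methylated/total read counts per CpG
per individual (as produced by reduced representation bisulfite sequencing,
RRBS). CpGs are filtered cohort-wide: median coverage across individuals in
[6, 200], no random/unplaced contigs, median methylation strictly between
0 and 100%. All interval logic is 0-based half-open.

## Region transformation

Counts are aggregated within annotation-defined regions: for individual
*i*, M<sub>i·</sub> = Σ<sub>j</sub> M<sub>ij</sub> and T<sub>i·</sub> =
Σ<sub>j</sub> T<sub>ij</sub> over the region's *k* CpGs, missing CpGs
contributing zero to both sums. The region score is the empirical-Bayes
shrunken fraction

    z_i = (M_i· + λ·p̄) / (T_i· + λ),   p̄ = Σ_i M_i· / Σ_i T_i·

with prior strength λ defaulting to the population median of T<sub>i·</sub>.
Individuals with no coverage receive exactly p̄; deeply covered individuals
keep essentially their raw fraction. The score therefore accounts for
missingness, coverage (measurement accuracy) and, through the sums, the
number of CpGs per region. Shrinkage never moves a score past the
population mean, and its magnitude is non-increasing in coverage — both
properties are tested. Post-hoc standardization is left to the global test
(below) rather than being baked into the score.

## Grouped global testing

Whether a *set* of regions (a genomic annotation, or the regions mapping to
a gene set) is associated with exposure is tested with a score-type
quadratic form

    Q = (e − ē)ᵀ Z̃ᵀ Z̃ (e − ē)

where `e` is the 0/1 exposure vector and Z̃ the feature matrix
(regions × individuals), column-centered, covariate-residualized if
covariates are supplied, and by default standardized to unit variance per
feature so CpG-rich or high-variance regions do not dominate. The null
distribution respects the pairing exactly: exposure labels are swapped
within pairs, exhaustively over all 2<sup>n_pairs</sup> assignments when
that is at most 2<sup>20</sup>, otherwise by 10,000 seeded Monte-Carlo
draws with the add-one (b+1)/(B+1) correction. Because each pair
contributes one exposed member, Q reduces to a quadratic form in the pair
Gram matrix of within-pair feature differences, which makes exhaustive
enumeration cheap. Validity (type-I error ≤ α up to enumeration
granularity) is checked empirically over 1,000 null simulations.

Pathway scans map regions to their nearest gene within 100 kb (ties broken
lexicographically) and test each gene set's regions; focal genes can be
excluded (with their regions) to keep a scan unbiased by the regions that
motivated it, and the collection can be restricted to sets containing a
focal gene. Benjamini–Hochberg adjustment runs across whatever collection
was tested.

## Per-region mixed models

Counts: a binomial logistic mixed model,
logit Pr(methylated) ~ exposure + CpG id (+ covariates), with a per-pair
random intercept and a per-pair random exposure slope, possibly correlated.
Using the read totals as binomial denominators is equivalent to modelling
each read as a Bernoulli outcome; because each pair has exactly one exposed
member, the random exposure slope doubles as an individual-level effect, so
one model covers single- and multi-CpG regions. Fitting is
Laplace-approximated maximum likelihood: penalized IRLS jointly over fixed
effects and random-effect modes inside a Nelder–Mead search over the
log-Cholesky factor of the 2×2 random-effect covariance. On small instances
(≤ 4 fixed effects and ≤ 80 observations) the Laplace solution is refined
by adaptive Gauss–Hermite quadrature (9×9 nodes centered and scaled at each
pair's conditional mode), because the Laplace approximation's O(1/T) bias
is visible there; tests verify agreement with an independent dense-grid
quadrature oracle to 10⁻³ on the log-odds scale. Wald p-values use the
normal reference; a likelihood-ratio option is available. Fits with a
random-effect standard deviation below 10⁻⁴ are flagged as boundary fits —
expected, not an error, at a few dozen pairs. Non-convergence and probable
separation (|log-odds| > 15) are flagged, never silently dropped.

Continuous platform values: the same fixed/random structure as a Gaussian
linear mixed model, fitted by REML (ML when model fits are compared, e.g.
for interaction likelihood-ratio tests). The implementation profiles the
residual variance and GLS fixed effects out of the criterion and optimizes
only the relative covariance factor. In the balanced complete case — one
observation per sibling, no covariates — the REML optimum is available in
closed form (the saturated per-pair covariance equals the unbiased sample
covariance), and the exposure Wald test with t(n_pairs − 1) degrees of
freedom then *is* the paired t-test; this equivalence is enforced to 10⁻⁶
relative tolerance in the tests. The t(n_pairs − 1) reference (the
between-within rule for a within-pair contrast) is used for all linear-model
exposure tests.

Interactions (exposure × conception date, exposure × sex, exposure ×
pre/post-window indicator) are tested by ML likelihood-ratio comparisons
always retaining main effects. Multi-locus models pool several regions by
replacing the pair exposure slope with an individual random intercept plus
a region-within-individual random effect; a single region degenerates to
the single-region model and is delegated to it.

## Multiple testing, replication and downstream analyses

Benjamini–Hochberg adjustment is used throughout (via statsmodels). The
replication rate of a validated region set is quantified by closed testing
with the Simes local test: the (1−α) lower confidence bound on the number
of true discoveries equals k minus the size of the largest subset whose
Simes test survives, computed with the sorted-p shortcut (replacing a
subset member by a larger p-value can only make Simes less significant, so
the hardest subset of each size consists of the largest p-values); an
exhaustive 2^k oracle verifies the shortcut in tests. The point estimate
π₁ is the same bound at α = 0.5 (median-unbiased). Enrichment uses the
two-sided Fisher exact test with the conditional-MLE odds ratio and exact
CI (scipy).

Cross-platform validation retains regions whose region-mean methylation
correlates at Pearson r > 0.7 between platforms across shared individuals.
Triplicate continuous measurements pass QC per cell when ≥ 2 of 3 wells
succeeded with s.d. < 10 percentage points (interpreting "10%" on the
0–100 methylation scale), per unit when the cross-cohort success rate
exceeds 75%, with SNP-overlapping units masked; retained cells are
triplicate means.

Phenotype association regresses region methylation (percent) on a
phenotype plus covariates, with a pair random intercept when both siblings
contribute and OLS when a phenotype exists in one exposure group only
(birth weight is recorded for the exposed series only); BH runs across the
region × phenotype grid.

## Synthetic data generator

The generator defines the study conditions under which everything is
tested: 24 same-sex pairs (half male), exposed LMP uniform on
1944-11-28..1945-05-15, control siblings conceived before/after in equal
numbers; bimodal baseline methylation (two beta components at means 0.08
and 0.90, high-mode weight 0.6488, giving a population mean of 61.2%);
per-individual logit offsets with s.d. 0.2, calibrated so the s.d. of
per-individual mean methylation is ≈ 1.7 points; negative-binomial depth
(mean 30, size 8, truncated at ≥ 1) yielding a realized median ≈ 28×;
0.998 per-CpG completeness; regions of log-normal length (median 1.4 kb)
carrying Poisson(6.7) CpGs. Planted effects: log-normal magnitudes with
median 4.6 percentage points, hypermethylated with probability 0.608, and
converted to logit offsets at each region's baseline so probabilities stay
valid; where the baseline is so extreme that the requested shift would
leave (0,1), the truth table records the realized (truncated) effect.
Effects are multiplied by a step window — 1 for conceptions before
1945-04-01, 0 at or after (an optional linear ramp exists). The continuous
re-measurement platform applies a configurable attenuation (default 0.7)
plus Gaussian well noise (s.d. 2 points) in triplicate with 5% failed
wells. Phenotypes are generated by inverting the target regression slopes
(3.9 %/kg for birth weight, exposed only; 2.4 %/(mmol/l) for LDL) so that
regressing methylation on the phenotype recovers them at low noise.

The pair random-effect s.d. (0.3 on the logit scale) is a free knob with
no published counterpart; it was set once to give realistic within-pair
correlation and adequate test power. Desk-scale defaults (24 pairs, 40
regions, 8 planted) keep the full pipeline and test suite in minutes; the
genome-scale study dimensions (1.2M CpGs, 90,451 regions) are not
reproduced and the tests consequently demonstrate statistical correctness
and calibration, not genome-scale performance. The generator does not
simulate reads, sequence context, enzyme-digest fragment structure, or
annotation biology: annotations are disjoint groupings of simulated
regions, so conclusions about overlapping real annotations rest on the
overlap-mapping tests, not the simulator.

## Numerical choices and degenerate inputs

- Random-effect covariances use log-Cholesky parameterizations with
  log-diagonals clipped to ±8; the same ridge (10⁻¹⁰) regularizes the
  covariance and its log-determinant so zero-variance boundaries stay
  finite.
- Inner PIRLS stops at gradient norm 10⁻⁸ (relative) with step halving;
  outer searches are Nelder–Mead with at most 500 iterations.
- Permutation ties count as exceedances (within 10⁻¹² relative), so the
  identity permutation always counts and p-values are in (0, 1].
- p-values are truncated to (0, 1]; degenerate inputs (all-zero coverage,
  constant exposure, zero-variance differences, zero-margin tables) raise
  or return flagged results rather than NaN surprises.
- Median over an even number of samples is the midpoint rule throughout.

## Known limitations

- The two-stage discovery design (annotation selection, then region tests
  within selected annotations) does not strictly control region-level FDR
  under the global null: a by-chance selected annotation contains regions
  pre-screened to look associated. On all-null simulations the mean
  false-discovery proportion tracks the stage-1 selection rate (≈ the
  annotation q threshold); the acceptance suite bounds it with binomial
  slack rather than pretending exact control.
- GLMM Wald inference uses the normal reference; at a few dozen pairs its
  CI coverage is near but not exactly nominal (the tests assert 90–98%
  over simulated regions).
- The linear-model degrees of freedom (n_pairs − 1) are exact for the
  balanced case and an approximation otherwise; no Satterthwaite or
  Kenward–Roger correction is implemented.
- Validation (`run_validation`) currently requires a simulation block: the
  continuous platform re-measurement is generated, not read from files.
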