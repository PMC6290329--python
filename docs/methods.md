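# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Data model and pipeline order

The unit of analysis is a genomic region (0-based, half-open) from a
consensus peakset. The pipeline runs in the order the original analysis ran:

1. consensus peakset from per-sample peak calls,
2. reads/kb and RPKM normalization,
3. correlation QC and sample exclusion,
4. empirical-Bayes batch adjustment on RPKM,
5. back-conversion to reads/kb,
6. per-region NB GLM testing with the three-contrast intersection call,
7. feature / motif / gene-set enrichment and pyrosequencing concordance.

### Consensus peaksets

Peaks from all samples are clustered by transitive >=1 bp overlap (a sorted
sweep; cluster coverage is contiguous, so the sweep finds exact connected
components) and each cluster is replaced by its union span. A sample
supports a region iff one of its peaks belongs to the cluster; regions with
support below `min_samples` (default 3) are dropped. The >=1 bp overlap
rule and union-span extent are declared conventions — the common defaults
for occupancy-based consensus building. Fragment counting assigns each
fragment to the region containing its midpoint; consensus regions are
disjoint, so the assignment is unique, and fragments outside all regions
are tallied in a discard counter.

### Normalization

reads/kb = count / (length/1000); RPKM divides by the sample's total reads
*in predicted peaks* over 10^6 (not total library size). The inverse
transform is exact, which the batch-adjustment round trip relies on.
Correlation QC uses Pearson correlation of log(RPKM+1) — the log stabilizes
the heavy right skew of enrichment data. A sample is flagged when its
nearest correlation neighbour carries a different tissue label (the
operational form of "clustered with the other tissue") or when its best
correlation falls below `min_r`. Exclusion happens before any group-aware
step. The PC scan reports, per principal component, the variance fraction
and a one-way ANOVA of PC scores on each categorical covariate; the
statistic is a declared choice.

### Batch adjustment

Standard parametric ComBat on log(RPKM + 0.5): per-region standardization
against a covariate-preserving linear fit, per-batch location (normal prior)
and scale (inverse-gamma prior, moment-matched) estimates shrunk by the
iterative EB solution, adjustment, rescaling, exponentiation. Two batch
factors (meDIP round, extraction round) are corrected sequentially in that
order. `shrink=False` disables the priors, reducing the method to a direct
per-region location–scale correction used as the testing oracle. The
adjustment is the exact identity when a factor has a single level. A rank
test rejects batch factors that are collinear with kept covariates, since a
confounded design cannot separate batch from biology.

Note that EB shrinkage does *not* vanish as regions grow: the shrinkage
weight is `t2*n / (t2*n + delta^2)`, governed by batch sample count and the
across-region heterogeneity of batch effects. The oracle route is therefore
the `shrink=False` flag, not a large-region limit.

### Dispersion and testing

All regions share one design matrix, so all NB GLM fits run as a single
batched IRLS (weighted least squares solved simultaneously across regions).
This is a performance choice only; per-region results match `statsmodels`
GLM fits to ~1e-4 (cross-checked in the test suite).

The common dispersion maximizes the Cox–Reid adjusted profile likelihood
summed over regions (means profiled at their IRLS fits, two alternating
cycles). The CR term — subtracting half the log-determinant of the weighted
information per region — matters: without it the estimate is biased low by
roughly df/n, which measurably inflates type I error. When dispersion is
estimated after batch adjustment, the CR/MoM design is extended with the
batch dummies so the degrees of freedom the adjustment consumed are not
mistaken for low dispersion.

`estimate_dispersion` also returns per-region method-of-moments estimates
shrunk toward the common value (prior weight 20 residual-df units,
declared). The pipeline, however, tests against the *common* value: on null
simulations the per-region moment estimates correlate with the contrast
noise and distort the size of the test (fraction of p < 0.05 ≈ 0.052
instead of 0.050, which a large pooled KS test detects), while the
common-dispersion LRT is calibrated to Monte-Carlo precision at 3x10^5 null
draws. The per-region estimates remain available as diagnostics.

Contrast p-values come from 1-df likelihood-ratio tests against the model
with the two contrasted groups merged; log2 fold changes come from the
full-model coefficients. Back-converted (non-integer) values are rounded
half-to-even before fitting by default; a continuous mode feeds them to the
NB likelihood as pseudo-counts. BH is applied within each contrast across
regions; NaN p-values (non-converged fits, counted) pass through without
entering m. The exposure-specific call requires q < alpha in both PAE
contrasts and q >= alpha in PFvC; direction is assigned only when both PAE
contrasts agree in sign, and sign-discordant calls are counted separately so
up + down + direction-uncalled always equals the total. Fold change is the
symmetric ratio of the PAE mean to the average of the two control-group
means, classed at 1.5x and 2x. Tissue concordance keeps called regions
whose per-tissue log2FCs share a nonzero sign.

### Permutation enrichment

Feature and motif enrichment compare the observed statistic (per-feature
region count; per-motif fraction of regions with >=1 hit) to the same
statistic on `n_perm` uniform same-size subsets of the background peakset,
drawn without replacement, with the add-one (Phipson–Smyth) empirical
p-value — so p is in [1/(n_perm+1), 1] and never zero. Enrichment and
depletion one-sided p are both reported; the two-sided value is
min(1, 2*min of the pair). Because the null statistic is discrete, these
p-values are mildly conservative at small `n_perm`; calibration tests
account for this. Motif scanning scores log2-odds (pseudocount 0.01,
background = declared composition) at every offset on both strands, with a
hit threshold of 80% of the motif's maximum attainable score (configurable);
non-ACGT letters score as background (log-odds 0).

### Gene-score resampling

Gene score = −log10(minimum region p) over the gene's regions (regions map
to a gene by overlapping its body or either promoter window). A set's
observed statistic is the mean member score; the null is the mean of
same-size random gene draws (`iterations` = 10,000 by default), one-sided
for high scores, add-one corrected. Null distributions are shared across
sets of equal size — the draws depend only on size, so per-set p-values are
unchanged. The multifunctionality correction regresses score ranks on
rank-normalized per-gene annotation counts and re-runs GSR on the
residuals; with uniform annotation the correction is exactly the identity.
This residual-rank form is simpler than the original tool's internal
correction but monotone and identity-preserving; the per-set
"multifunctionality" column is the mean rank-normalized annotation count of
the set's members. A term is exposure-specific when p and corrected p both
clear alpha in the two PAE contrasts and at least one fails in PFvC.

### Pyrosequencing concordance

Group summaries average per-animal DMR means (mean over available CpGs,
flagged when incomplete) within group, per age or pooled. The mean-change
CI is change ± 1.96·se; the published summary's spread column behaves
arithmetically as a standard error and the parameter is named `se`
accordingly. Because the published pooled change does not equal the
difference of the printed pooled means, the pooled change is reported under
both conventions (mean of per-age changes, and pooled-mean difference).
The biological-significance flag is strictly |change| > 5 percentage
points. Per-CpG testing uses Welch's t within age strata and OLS with an
age covariate when pooled (the original test is unstated). Direction
concordance compares the sign of the pyro change with the region-level
log2FC; a zero on either side is indeterminate.

## The synthetic generator

`generate_counts` draws NB counts (gamma–Poisson; variance
mu + alpha·mu²) with log-mean = per-region baseline (Normal(log 100, 0.5))
+ scalar age and breeding shifts + per-region tissue signature
(Normal(0, tissue_shift)) + per-region batch location shifts
(Normal(0, batch_shift_sd) per batch level) + optional per-batch residual
scale noise + the planted group effect. PAE-specific regions shift the PAE
group only; PF-shared regions shift PAE and PF jointly; the truth table
records status, direction, and true log2FC. Default design: 3 groups x
4 ages x n=4 (hypothalamus) and 3 groups x 2 tissues x n=4 at P22, with a
4-level breeding factor; batch factors are crossed with group and age so
that covariates stay estimable after correction (a deliberately friendlier
layout than the partially confounded original; the confounded case is
reproducible with a custom design table and is rejected by the rank test
when fully confounded). Sequencing depth is desk-scale (mean ≈ 100 reads
per region), chosen for test-suite speed, not realism.

Each generator draws from a named RNG substream of the master seed
(`SeedSequence([seed, crc32(name)])`), so adding a generator never perturbs
another's output, and identical seeds reproduce outputs bit-for-bit.

What the generator does not emulate: read-level alignment and peak-calling
artifacts, fragment-length chemistry of the immunoprecipitation, genome
sequence context (CpG density does not modulate counts), hydroxymethylation,
and correlated region-region structure. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
declared generative model, not performance on real sequencing data — in
particular the published headline counts depend on the deposited raw data
and are not reproducible at desk scale; the validation suite instead checks
in-table arithmetic and operating characteristics (sensitivity, FDR,
calibration) on data with known truth.

## Problem sizes and tolerances

The validation suite runs the full pipeline at 5,000 regions with 20 null
seeds, 10 recovery seeds, and 5 confound seeds — chosen so the whole suite
completes in a couple of minutes while the pooled null holds 3x10^5 p-value
draws. Permutation calibration uses 200 permutations over 500 replicate
subset draws. IRLS converges at relative log-likelihood change < 1e-8 (max
60 iterations; non-converged regions are flagged, p = NA). Dispersions are
clipped below at 1e-8; fold-change computation exposes an epsilon for zero
means; batch adjustment floors pooled variances at 1e-12.

## Known limitations

- The batch adjustment followed by a count model is the published chain but
  statistically heterodox: adjusted values are no longer integer counts and
  slightly under-disperse. The rounding rule plus the batch-df-aware
  dispersion estimate keep the end-to-end test calibrated on synthetic
  nulls, but the chain's behaviour on real data with strong batch-treatment
  interaction is not guaranteed.
- "Not significant in PFvC" (q >= alpha) is an acceptance of the null, not
  evidence for it; regions with borderline PFvC q flip between called and
  uncalled under resampling.
- The multifunctionality correction is a transparent reimplementation of
  the idea, not a replica of the original tool's internals; its per-set
  multifunctionality column is defined here, and agreement with the
  original tool's column values is not expected beyond rank order.
- Sequential (not joint) correction of the two batch factors is a declared
  convention; with crossed factors the difference is second-order.
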