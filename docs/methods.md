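# Methods

`methylpanel` analyses targeted bisulfite-sequencing panels — cytosine-level
methylated/unmethylated read-count matrices over a curated gene panel (the
motivating design is an autophagy–lysosomal-pathway panel profiled in
case/control cohorts) — from quality control through per-cytosine
differential modelling, enrichment statistics, cross-dataset rank
aggregation, epigenetic aging rates, and concordance analyses. A synthetic
generator with known ground truth stands in for sequencing data, so every
stage has a parameter-recovery and null-calibration surface.

## Data model and coordinates

A dataset is a pair of integer matrices M (methylated reads) and U
(unmethylated reads), cytosines × samples, with absent cells encoded as
missing rather than zero; coverage is M + U and the beta value is
B = M / (M + U). Cytosines are keyed by (chrom, pos, strand, context) with
1-based positions; all interval inputs (genomic elements, SNP masks) are BED
0-based half-open, converted only at the reader boundary. A cytosine at
1-based position p lies in [start, end) iff start < p ≤ end. Sample
covariates (diagnosis group, age, sex, postmortem interval, batch, replicate
group, numeric extras such as cell-type proportions) drive every design
matrix.

## Preprocessing

Stages run in a fixed order, each logged in a telescoping QC report:

1. **Coverage filter** — cells with depth < `min_coverage` (default 30×)
   become missing.
2. **Replicate QC and merge** — technical replicate groups whose pairwise
   beta-value Pearson r ≤ `replicate_min_r` (default 0.9) lose the member
   with the lower median coverage (both members are reported; groups with
   unassessable correlation are retained with a warning). Surviving groups
   collapse by cell-wise averaging of M and U over non-missing members,
   rounded half-up.
3. **Site filters** — sites observed in < 70% of samples; sites whose every
   observed call is 0%; sites inside the user-supplied common-SNP mask.
4. **Quantile normalisation** (optional, `normalize`) — M and U are
   normalised independently. The reference distribution is the cross-column
   mean of each column's empirical quantile function at midpoint plotting
   positions; with equal observed counts this is exactly the classic
   mean-of-sorted-columns reference. Ties receive the average of their
   positions' reference quantiles; missing cells are skipped and restored;
   results are rounded half-up. Rank order within a column is preserved.
5. **Stable-site filter** — sites whose calls are 0%, 100%, and/or missing
   in ≥ 50% of samples (boundary inclusive) are removed. This pass runs
   after normalisation.
6. **Sample outliers** — PCA of the beta matrix (per-site mean imputation is
   used solely here); samples deviating > 3 SD from the mean of PC1 or PC2
   scores are excluded, in a single pass. A duplicated sample always shares
   its twin's flag status; note that when a duplicate pair dominates the
   variance (G ≫ n) both members can legitimately be flagged.

## Differential model

**m-values.** Betas are shrunk towards the centre, B′ = (B·(f−1) + 0.5)/f,
and transformed to m = log2(B′/(1−B′)); f defaults to 1000, or 2000 for
datasets containing CpH sites (whose more extreme betas need stronger
shrinkage). The transform is strictly increasing and m_to_beta
(B = 2^m/(2^m+1)) inverts it exactly on the shrunk scale, within 0.5/f of
the original B.

**Design.** Intercept + diagnosis (case = 1) + age, sex, postmortem
interval, batch (categoricals dummy-coded, constants dropped, aliased
columns pruned), optional diagnosis×age interaction, plus surrogate
variables. Contrasts are arbitrary linear combinations of coefficients.

**Surrogate variables.** Each cytosine's m-values are regressed on the
known covariates; PCA of the residual matrix fixes the number of components
(all with variance share > 5%, capped so the design keeps residual degrees
of freedom) and their site-space directions. The sample scores are then
re-estimated by projecting the per-site-centred *original* m matrix onto
those directions. The projection step matters: residual-PC scores are
orthogonal to every modelled covariate by construction, so they can never
carry the covariate-correlated share of a confounder — including them
leaves the group coefficient untouched while shrinking the residual
variance, which worsens miscalibration under latent-factor structure. With
the projection, a planted cell-mixture-like factor or a
diagnosis-confounded batch is recovered (|r| > 0.8 with the hidden label)
and the type-I error returns to nominal. This construction is a documented
simplification of iterative surrogate-variable analysis; it shares SVA's
fundamental limit that a confounder perfectly collinear with the contrast
cannot be separated from it.

**Robust fit.** Per-cytosine M-estimation with the Huber ψ (c = 1.345),
iteratively reweighted least squares vectorised across cytosines, scale
re-estimated each iteration as 1.4826 × MAD of residuals, convergence at
max coefficient change < 1e−6 or 100 iterations. Cytosines whose observed
design is rank-deficient or has fewer than rank + 2 complete cases are
skipped and logged. The residual SD used downstream is the Huber ψ-based
estimator with the Street–Carroll–Ruppert small-sample correction (the
estimator MASS's `summary.rlm` pairs with (X′X)⁻¹ standard errors): it is
consistent at the normal and far less noisy than the raw MAD scale, whose
sampling noise violates the chi-square behaviour the empirical-Bayes step
assumes and measurably inflates type-I error.

**Empirical-Bayes moderation.** A scaled inverse-chi-square prior
(d0, s0²) is moment-matched to the sample variances on the log scale
(digamma/trigamma corrections; trigamma inversion by Newton iterations;
d0 capped at 1e7, with s0² set to the mean variance, when the variances are
essentially identical). Posterior variance s̃² = (d0·s0² + df·s²)/(d0 + df);
the moderated t is effect/(s̃ × unscaled SE) on df + d0 degrees of freedom,
two-sided. Benjamini–Hochberg controls FDR; q < 0.05 is "significant"
throughout.

**Percentage-point effects.** Fitted m-values are back-transformed to betas
and the same design is refitted by ordinary least squares; the contrast
coefficient × 100 is the effect in percentage points of methylation per
unit covariate (per year for age contrasts). This is the scale on which
planted effects are specified, so recovery is directly comparable.

## Enrichment statistics

Every enrichment is an odds ratio of a 2×2 table with Fisher's exact test:
sample OR = ad/bc (infinite when bc = 0); two-sided p by the
point-probability rule; 95% CI by the Woolf log-OR normal interval with a
Haldane 0.5 correction when any cell is zero. Constructions:

- **Direction**: {significant vs not} × {hyper vs hypo}.
- **Genomic elements**: per class, {significant (optionally restricted to a
  direction) vs rest} × {inside vs outside}; membership is the interval
  union and is counted independently per class. Elements covering no panel
  site are reported without a test.
- **TSS-distance bins**: unsigned distance to the nearest panel-gene TSS,
  20-kb half-open bins (distance exactly 20 000 falls in the second bin);
  per gene stratum (default lysosome vs rest), within-bin vs outside-bin.
- **Pathways**: cytosines are assigned to the nearest panel gene whose
  probe window contains them (lexicographic gene-id tie-break);
  {significant vs not} × {pathway genes vs rest}. A pathway equal to the
  whole panel leaves the comparison column empty; the degenerate table is
  reported with p = 1 and no OR.
- **Per-gene statistics**: one-sided (greater) Fisher test of
  significant-site density in the gene versus all other interrogated sites
  (the gene's own sites are excluded from the background cells so the 2×2
  partitions cleanly). The gene's direction is the majority sign of its
  significant cytosines; ties (including zero significant sites) resolve by
  the sign of the weighted mean fold change over all the gene's cytosines,
  weights −log10(p). The weighted mean percentage-point change (wmfc) is
  reported.
- **Gene-set overlap**: membership 2×2 over a gene universe, two-sided.
- **Top-site element concordance**: per element class, each instance is
  tested for containing a top-k (default 5000) most-significant site of
  each dataset (intervals optionally expanded ±1 kb for cross-tissue
  promoter/enhancer matching); the 2×2 over instances {top in A} × {top in
  B} measures concordance.

## Rank aggregation

Genes are ranked per dataset by their one-sided gene-level enrichment p
(average ranks for ties, normalised by the number of ranked genes; genes
absent from a dataset receive the uninformative-worst rank 1.0). For a
gene's ascending rank vector r over k datasets, the score is
ρ = min_j Beta(j, k−j+1).cdf(r_(j)) — the smallest upper-tail probability
that at least j of k uniform ranks fall at or below r_(j) — with the
Bonferroni-style adjustment p_adj = min(1, ρ·k). ρ is monotone (improving
any rank never raises it), reduces to the input ranking for k = 1, and the
adjustment is conservative under the null.

## Aging

The age model is the differential engine with diagnosis, age and their
interaction; group-specific slopes are contrasts (control = age coefficient,
case = age + interaction), BH-adjusted within each contrast, reported in
percentage points per year. The per-gene aging rate is the
−log10(p)-weighted mean of the gene's cytosine slopes, forced to zero when
no cytosine reaches age-effect q < 0.05. Group comparisons: overlap of
non-zeroed genes (two-sided Fisher over the shared universe), direction
agreement among jointly non-zeroed genes ({case sign} × {control sign}
Fisher), and a paired t-test on absolute rates over jointly non-zeroed
genes. The age/disease correlation restricts to loci nominally significant
(p < 0.05, unadjusted) in both tables and correlates absolute effects.

## Concordance

Kendall tau-b (tie-corrected) on paired per-gene odds ratios, exact null
for n ≤ 8 without ties, optionally through a one-to-one homolog map
(many-to-many candidates reduced by highest combined site count). Weighted
Pearson correlation with −log10(p) weights and a t-approximation on the
effective sample size (Σw)²/Σw². The exacerbation test compares effect
magnitudes of two contrasts over shared cytosines: {|effect A| > |effect B|}
× {differentially methylated vs not}; "differentially methylated" defaults
to significance in the A contrast (configurable to union or intersection —
note that the A-referenced rule is mechanically enriched when the two
contrasts are unrelated, since it conditions on A's own hits).

## Synthetic data generator

The generator emulates a padlock-probe panel: genes spaced along one
chromosome, 5–30 CpGs uniformly placed within ±10 kb probe windows around
each TSS, promoter/1–5 kb/exon/intergenic element intervals, and one of the
five autophagy–lysosomal pathway labels per gene (80% of genes).

Per cytosine i and sample j the cell mean is the baseline
b_i ~ Beta(2, 2) (clipped to [0.02, 0.98]) plus the total planted shift in
percentage points — case effect δ_i, age slope γ_i·(age − midpoint), batch
offset, latent-factor contribution — divided by 100 and clamped to
[1e−3, 1−1e−3]; the clamped fraction is reported and warned about above 1%.
This is the exact logistic realisation of the logit-scale equivalent of a
percentage-point shift, so planted effects are directly comparable to the
pipeline's output. Case effects are planted at a fraction of genes
(optionally restricted to one pathway and one element class), on a fraction
of each gene's cytosines, with a constant sign per gene drawn hyper with
probability `hyper_fraction`; effects are planted only at cytosines whose
baseline can absorb the full shift, so the truth table equals the realised
simulation. Coverage is negative-binomial (gamma–Poisson; mean 100,
dispersion 5 → CV ≈ 0.47); methylated counts are beta-binomial with a
single intra-class correlation ρ (default 0.01 — chosen so planted effects
at the recovery scale are detectable while keeping the overdispersion that
makes binomial-only inference anticonservative; it is not calibrated to any
real dataset). Technical replicates redraw counts at identical cell means;
outlier samples receive a global mean shift of `outlier_shift_sd` (default
6) SDs of the per-sample mean methylation, floored for degenerate designs.
Batch offsets are per-(site, batch) normal draws in percentage points; an
optional `batch_confounding` tilt makes cases favour later batches —
without it a random batch only adds within-group variance that the standard
errors already cover and does not inflate type-I error. Latent factors have
normal per-site loadings (percentage points) and per-sample scores. One
seed drives fixed, independently spawned substreams per stage, so enabling
one feature never perturbs another's draws; `panel_seed` optionally pins
the panel layout so several datasets form one multi-tissue study.

What the generator does not emulate: read-level bisulfite conversion
errors, probe capture bias, strand-specific hemimethylation, spatially
correlated methylation along the genome, and realistic bimodal
genome-wide methylation landscapes (baselines are unimodal around 0.5).
Passing tests therefore demonstrate the statistical machinery on an
idealised count model, not performance on real padlock data.

## Problem sizes and numerical choices

The acceptance checks run at ~5000 cytosines and 20 + 20 samples (the
package's standard demonstration scale; the end-to-end demo completes in
seconds). The directional null-calibration arm runs with 500 affected genes
because effect signs are constant within genes, making genes the
independent sign units: the ±25% OR band corresponds to ≈ 2.5σ at that
count and would be uninterpretable at 29 genes. Monte-Carlo oracles use
10⁶ draws with 3-SE tolerances. Fisher p-values are validated against
exhaustive hypergeometric enumeration for every table with all margins
≤ 30 (tolerance 1e−10). Degenerate inputs: all-zero 2×2 tables, empty gene
universes, constant ages, and unsortable rank vectors raise validation
errors; constant Kendall inputs and zero-variance weighted correlations
report as undefined rather than erroring.

## Known limitations

- The surrogate construction cannot repair a confounder collinear with the
  contrast of interest (no method can without external information).
- The stable-site and call-rate filters interact with the generator's
  baseline distribution; panels with many near-0/near-1 cytosines will lose
  a larger fraction of sites than the defaults suggest.
- The percent-change refit reports the linear-projection coefficient of the
  back-transformed fitted values; for very large effects at extreme
  baselines this understates the planted beta-scale shift.
- Gene assignment uses the nearest in-window TSS only; sites inside two
  overlapping probe windows go to the nearer gene, not to both.
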