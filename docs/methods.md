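# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `admixclock`.  The package analyses a
two-population epigenetic-aging study design: an indigenous-role group
(`groupA`) and an admixed-role group (`groupB`) living in one locality, 24
individuals each, profiled for CpG methylation (beta values), genome-wide
genotypes, local ancestry, kinship and inbreeding.

## Clock engine

All estimators are linear in beta values: `score = b0 + Σ_j b_j β_j`.  Two
output transforms are supported: `identity` (the score is already in output
units) and `horvath`, the piecewise map used by the well-known online age
calculators, whose inverse is

    F⁻¹(x) = (1 + a)·exp(x) − 1   for x ≤ 0
    F⁻¹(x) = (1 + a)·x + a        for x > 0

with adult-age knot `a = 20` years (configurable; the convention follows the
calculator lineage, which does not itself print these constants — they are a
documented design decision here).  The map is continuous and monotone, and
`F⁻¹∘F` is the identity on positive ages, which the test suite checks by
property.

Missing clock CpGs are imputed with the cohort mean beta for that CpG
(fallback 0.5), with a configurable 50% coverage floor; mean imputation
preserves the score scale, which matters because the acceleration residual
is computed cohort-internally.

*Age adjustment.*  Acceleration = OLS residual of the estimate on
chronological age over the whole cohort.  Residuals are mean-zero and
age-orthogonal by construction — an algebraic fact with a consequence that
shapes the generator (below).  IEAA regresses additionally on
cell-composition fractions (one simplex column dropped; zero-variance
columns are dropped with a warning rather than failing, so degenerate
fractions reduce gracefully to plain age adjustment).  EEAA z-scores the
Hannum-type estimate and three age-associated cell measures, combines them
with configurable weights (default equal — the literature defines the
weights in cited work, not in a form reusable here), rescales to the
estimate's units and age-adjusts.

## Synthetic cohort

Design constants are the study's: 24 per group, 12 F / 12 M, 50% infected
balanced by sex, ages Normal(39.2, 12.9) and Normal(41.1, 14.0) years
truncated at 18 (adult cohort; also keeps the horvath transform in its
linear branch), rural/urban 20/4 in groupA and 0/24 in groupB.
Cell-composition fractions are Dirichlet over six blood cell types.

*Planting medians in residual space.*  Because acceleration residuals are
mean-zero over the joint cohort, an asymmetric pair of group medians (e.g.
+0.87 / −1.67 yr) cannot be produced by adding constant offsets to DNAm age:
joint residualization would recentre them symmetrically.  The generator
therefore constructs the per-clock shift vector directly in the admissible
subspace — orthogonal to the intercept and to age — with the requested group
medians.  Each group's block starts as Normal(0, 3 yr) deviations (the 3-yr
acceleration SD is a free scale chosen as typical for blood-based clocks);
its median is set by a constant shift and its mean by moving only values
strictly above/below the middle order statistics (the skew an asymmetric
median pair requires lives in the tails); alternating this with projection
onto the orthogonal complement of span{1, age} converges to ~1e−9 in a few
dozen iterations.  The clock engine then recovers the planted medians
exactly up to beta noise.

*Exact clock inversion.*  For a target value t, the required linear
predictor is spread across CpGs as `β_j = (1 + u·sign(b_j)) / 2` with
`u = (F(t) − score(β=0.5)) / (Σ|b_j|/2)`, which is exact and stays in
[0, 1] whenever t is inside the clock's designed range (18–90 yr with a
1.5× margin).  At `noise_sd = 0` the engine recovers chronological age to
machine precision, making engine correctness testable to numerical
precision; the default `noise_sd = 0.01` beta units adds ≈ 0.1 yr of
median error for a 71-CpG clock.  CpGs belonging to no clock are
Beta(0.5, 0.5) background, the bimodal marginal typical of array
methylation.

*What the generator does not emulate:* probe-specific artifacts, cell-type
deconvolution error, batch effects, LD between clock CpGs and genotypes
(meQTLs), and any real correlation between acceleration and genotype.
Passing tests therefore demonstrate the correctness of the statistical
machinery under the stated generative model, not the biological claims on
real cohorts.

## Admixture simulation and the deviation scan

Ancestral allele frequencies follow the Balding–Nichols model
(Beta((1−F)p/F, (1−F)(1−p)/F) around a shared base frequency, default
FST = 0.15 for a Native-American/European-like divergence).  Haplotype
ancestry tracts follow a two-state Markov process: between adjacent SNPs
the state is redrawn from the stationary distribution (AMR weight 0.55)
with probability `1 − exp(−ρ·d)`, with `ρ = 15` switches per morgan
(≈ generations since admixture for a colonial-era event) and `d` from a
uniform 1 cM/Mb map.  The desk-scale genome is 5,000 SNPs on 10
chromosomes at 200 kb spacing — 100 cM per chromosome, 10 morgans total —
chosen so tract lengths (~30 SNPs) are short relative to the genome, as
they are in the real data, rather than spanning whole chromosomes.  One
enriched region (default 150 SNPs on chr5) is planted by forcing each
haplotype's tract there to AMR with probability `excess/(1 − q)`, which
raises the expected AMR frequency by exactly `excess`.

Posterior confidence is emulated directly: with probability 0.9 the true
ancestry's posterior is drawn above the 0.9 collapse threshold, otherwise
below it, so ≈ 10% of haplotype/SNP cells collapse to `UNK`.  The long
posterior table and the hard calls are generated from the same draws, so
`collapse_posteriors` on the table reproduces the calls exactly (tested).

*Scan conventions.*  `f_anc` excludes `UNK` haplotypes from the denominator
(a config switch can include them); μ and σ are the mean and sample SD
(ddof = 1) over unmasked SNPs genome-wide — the SD convention is not
dictated by the Z-score definition and is a documented choice; regions
require ≥ 2 consecutive same-signed SNPs beyond |Z| = 3 ("windows of
consecutive SNPs" implies plurality).  An optional outlier rule excludes
samples whose global ancestry fraction is > 3 SD from the cohort mean
(off by default).

*Calibration caveat.*  Tracts autocorrelate `f_anc` along the genome, so
the count of |Z| > 3 SNPs in one genome is over-dispersed relative to
binomial (exceedances arrive in runs).  The calibration test therefore
pools independent seeds and uses a 3σ band with σ the larger of the
empirical seed-to-seed SEM and the pooled binomial SE; pooled over 25
genomes the observed rate matches 2(1 − Φ(3)) ≈ 0.0027 closely.

## Genotype QC

Filter order mirrors the standard narrative: sample call rate → SNP call
rate → exact HWE → relatedness → ambiguous-SNP removal → LD pruning.
Thresholds are strict inequalities (a sample at exactly 5% missing
survives).  The exact HWE test conditions on allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one (computed in log-space with a float-tie slack of 1e−12; monomorphic
SNPs return p = 1 by convention).  PiHat is the classic method-of-moments
IBS decomposition, clipped to the probability simplex; SNPs with frequency
0 or 1 are excluded as uninformative.  Relatedness pruning is greedy: the
higher-missingness member of each offending pair is removed (ties broken
lexicographically — which member the original analysis removed is not
stated anywhere, so this is an explicit artifact decision).  LD pruning
computes composite (dosage) r² in 50-SNP windows advancing by 5, dropping
the later-positioned SNP of each offending pair, and repeats the scan until
a pass removes nothing, making the kept set a fixpoint (pruning twice
equals pruning once).

## Group comparison and downstream tests

The gate: Shapiro–Wilk at α = 0.05 in both groups (the analysis convention
names the test but not its α; 0.05 is the field default) → Welch t-test if
both pass, else two-sided Mann–Whitney (exact enumeration when both n ≤ 10
and no ties, tie-corrected normal approximation otherwise).  Both tests are
always computed and reported; the gated one provides the headline p.  BH
step-up controls FDR at q < 0.1 across estimators.  Estimator independence
is the connected-component structure of the Spearman-correlation graph at
p < 0.01.  Null simulations (1000 reps, 24 + 24) confirm the gate+test
type-I error stays at or below the nominal 5%.

Replication regressions are simple OLS of the estimator on the oriented
enriched-allele dosage without covariates by default (covariates can be
passed); monomorphic SNPs are skipped.  LD sharing among replicated SNPs is
reported at pairwise dosage r² ≥ 0.8.

## Kinship delta and inbreeding

Delta is the absolute difference of two individuals' estimator values (the
expectation "lower when related" is only meaningful for a magnitude).  The
naive pair-level correlation of delta with PiHat ignores that pairs sharing
an individual are dependent, so a label-permutation p (permuting
individuals, rebuilding the full delta table, 999 permutations by default)
is reported alongside and is the recommended inference.  By default the
association uses within-group pairs (the indigenous-role group, whose
demographic history motivates the analysis); a flag extends it to all
pairs.  Inbreeding associations report both Pearson and Kendall with BH
correction at the stricter q < 0.01 used for this analysis family.

## LMG decomposition

Exact subset enumeration (2^p OLS fits with centered R²), p ≤ 15 guarded
(the three model configurations have p ≤ 4).  Shares below −1e−12 raise an
error; tiny negatives are floored to zero before normalization.  The three
model frames encode: joint — Pop (1 = indigenous-role), Female, T.cruzi;
groupA-only — Inbreed, Paraje (1 = urban), Female, T.cruzi; groupB-only —
EUR, AMR, Female, T.cruzi, with an explicit near-collinearity check on
EUR + AMR (they are complementary up to minor ancestries).  Both raw
(summing to R²) and normalized (summing to 1) shares are emitted, plus the
top predictor's share of total variance (normalized share × R²).

## Problem sizes and determinism

Default problem sizes — 48 samples, ~2,100 clock CpGs plus 200 background,
5,000 SNPs, 96 haplotypes, 100-seed recovery studies, 1000-rep null
calibrations — were chosen so the full test suite and the acceptance script
run in minutes on a single core while keeping every calibration inside its
sampling-error band.  All generators take explicit seeds; the pipeline
spawns per-stage streams from one root seed, and two runs with the same
configuration produce byte-identical output bundles (tested).

## Known limitations

- File-driven orchestration is partial: `run_pipeline` covers synthetic
  mode; on real data the stage functions are called directly with tables
  read via `io_formats` (the CLI subcommands wrap exactly that).
- The EEAA composite's weights and cell definitions are configurable
  approximations; the generator plants the extrinsic clock as a standalone
  age-kind clock rather than through the composite, because planting an
  exact median through a weighted average of noisy components is ill-posed.
- The moment PiHat assumes homogeneous allele frequencies; it is not an
  ancestry-adjusted kinship estimator, only a consumer-compatible stand-in
  for one.
- p > 15 LMG (sampling approximation) is not implemented.
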