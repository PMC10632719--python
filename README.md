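# admixclock

Epigenetic clocks consistently report that some human populations are
"epigenetically older" than their neighbours, but separating genomic history
from ecology in such comparisons requires a chain of analyses that is rarely
packaged reproducibly: clock-based age-acceleration estimation, gated group
testing with FDR control, genotype quality control, local-ancestry deviation
scanning (admixture mapping) with GWAS-catalog discovery/replication,
kinship/inbreeding association, and variance-importance attribution.

`admixclock` implements that chain as a tested Python library for the study
design where two co-located populations — one indigenous, one admixed — of 24
individuals each (12 female / 12 male, half infected by a parasite, balanced
by sex, with an urban/rural split) are profiled for DNA methylation and
genome-wide genotypes.  Because cohort data of this kind are rarely
deposited, the package ships a first-class synthetic-data generator that
emulates the study's statistical structure, so every stage is exercisable and
testable end to end without downloads.

## The statistics at the core

**Age acceleration.**  Every estimator is a linear clock over CpG beta
values, `score = b0 + Σ_j b_j β_j`, optionally passed through the piecewise
log/linear age transform `F⁻¹(x) = (1+a)eˣ − 1` for `x ≤ 0`, `(1+a)x + a`
otherwise (adult-age knot `a = 20`).  The acceleration is the OLS residual of
DNAm age on chronological age; positive residuals mean epigenetically older
than the cohort trend.  Extrinsic (EEAA) and intrinsic (IEAA) variants
incorporate or remove blood-cell-composition covariates.

**Ancestry deviation scan.**  From per-haplotype local-ancestry calls
(posterior-collapsed at > 0.9), the per-SNP frequency `f_anc` of an ancestry
is standardized genome-wide, `Z_anc = (f_anc − μ_anc) / σ_anc`, with
two-sided normal p-values; regions are maximal runs of ≥ 2 consecutive
same-signed SNPs with `|Z| > 3`.  Catalog SNPs inside called regions with
p < 0.01 are candidates; replication is per-SNP OLS of the estimator on
the enriched-allele dosage at nominal p < 0.01.

**LMG importance.**  For each linear model the R² is decomposed exactly over
predictors by the Lindeman–Merenda–Gold (Shapley) statistic,
`LMG_k = Σ_{S ⊆ others} s!(p−s−1)!/p! · [R²(S∪{k}) − R²(S)]`,
with the top predictor's share of total variance reported as
`lmg_norm[top] · R²`.

**Genotype QC.**  PLINK-style cascade: per-sample call rate (mind 0.05),
per-SNP call rate (geno 0.05), exact Hardy–Weinberg test (p < 7.00e−08),
method-of-moments IBD PiHat with greedy pruning above 0.25, strand-ambiguous
A/T and C/G removal, and sliding-window LD pruning (50 SNPs, step 5,
r² > 0.2).

## Worked example

```python
import pandas as pd
from admixclock import clock_engine, group_comparison, synthetic_data as sd

spec, plan = sd.paper_preset()
cohort = sd.gen_cohort(spec, seed=11)
clocks = [sd.gen_clock(name=n, seed=100 + k, **kw)
          for k, (n, kw) in enumerate(plan.items())]
betas = sd.gen_betas(cohort, clocks, spec, noise_sd=0.01, seed=12)
est = clock_engine.compute_all(betas, clocks, cohort)
groups = pd.Series(cohort["population"].to_numpy(), index=cohort["sample_id"])
print(est.groupby(groups).median().round(2))
```

prints the per-group median accelerations (years) recovered by the full
betas → clock → residual pipeline:

```
        horvath_like  hannum_like  eeaa_like  pheno_like  grim_like
groupA          0.04         0.91       1.26        1.21       0.40
groupB         -0.10        -1.64      -2.53       -2.58      -1.15
```

The generator planted medians of (0.00, 0.87, 1.26, 1.19, 0.42) in the
indigenous-role group and (0.00, −1.67, −2.55, −2.62, −1.16) in the
admixed-role group; the recovered values agree within the beta-noise-driven
median error (≈ 0.1 yr).  A positive Hannum-type median in groupA and a
negative one in groupB is exactly the asymmetry the comparison stage then
tests (`group_comparison.compare_all`, Welch t or Mann–Whitney gated by
Shapiro–Wilk, BH FDR at q < 0.1).

The whole pipeline — simulation, QC, clocks, comparison, scan, replication,
importance, kinship — runs as one deterministic bundle:

```sh
admixclock --seed 1 --out-dir out run-all
```

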