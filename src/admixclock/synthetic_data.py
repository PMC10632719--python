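"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator emulates a two-population study set in one locality: an
indigenous-role group (groupA) and an admixed-role group (groupB), 24
individuals each (12 female / 12 male, half infected, balanced by sex),
with group ages drawn from Normal(39.2, 12.9) and Normal(41.1, 14.0) years
truncated at 18, an urban/rural split of 4/20 in groupA and 24/0 in groupB.

Methylation betas are constructed by *exactly inverting* each linear clock
for a per-sample target value and then adding noise, which makes clock-engine
correctness testable to numerical precision at zero noise.  Per-group
acceleration medians are planted directly in the residual space (orthogonal
to the intercept and age), so the downstream regression recovers them.

Admixed genotypes come from two Balding–Nichols ancestral panels with a
two-state Markov ancestry-tract process (uniform 1 cM/Mb map); one
ancestry-enriched region can be planted by boosting the probability that a
haplotype's tract in that window is from the enriched ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock_engine import age_transform
from .io_formats import (ClockDefinition, GenotypeMatrix, LocalAncestryCalls,
                         UNKNOWN_ANCESTRY, validate_sample_table)

CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")
_CELL_ALPHA = (3.0, 6.0, 2.0, 2.0, 2.0, 8.0)
_NON_AMBIGUOUS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]

# score-scale design constants: clocks are scaled so betas in [0, 1] span
# ages 18..90 with a 1.5x safety margin
_AGE_LO, _AGE_HI = 18.0, 90.0
_SCALE_MARGIN = 1.5


@dataclass
class CohortSpec:
    """Design constants of the emulated cohort (defaults mirror the study design)."""

    n_per_group: int = 24
    n_female_per_group: int = 12
    infected_fraction: float = 0.5
    age_mean_sd: dict = field(default_factory=lambda: {
        "groupA": (39.2, 12.9), "groupB": (41.1, 14.0)})
    rural_counts: dict = field(default_factory=lambda: {"groupA": 20, "groupB": 0})
    # estimator name -> (median acceleration groupA, median groupB), years
    planted_accel_shifts: dict = field(default_factory=dict)
    accel_sd: float = 3.0  # SD of individual acceleration around the group median
    min_age: float = 18.0

    def validate(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be >= 0")
        if self.n_female_per_group > self.n_per_group:
            raise ValueError("more females than samples per group")
        n_inf = self.infected_fraction * self.n_per_group
        if abs(n_inf - round(n_inf)) > 1e-9:
            raise ValueError(
                f"infected_fraction * n_per_group = {n_inf} is not an integer")
        for g, (mu, sd) in self.age_mean_sd.items():
            if sd <= 0:
                raise ValueError(f"age SD for {g} must be > 0")
        for g, r in self.rural_counts.items():
            if r < 0:
                raise ValueError(f"rural count for {g} must be >= 0")


@dataclass
class AdmixtureSpec:
    """Two-way admixture simulation parameters."""

    n_snps: int = 5000
    n_chroms: int = 10
    fst: float = 0.15
    global_amr_fraction: float = 0.55
    tract_rate: float = 15.0          # expected ancestry switches per morgan
    spacing_bp: int = 200_000         # uniform SNP spacing; 1 cM/Mb map
    enriched_region: tuple | None = ("chr5", 150, 300, 0.25)  # (chrom, start_idx, end_idx, excess)
    posterior_confidence: float = 0.9  # P(posterior clears the collapse threshold)

    def validate(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0, 1)")
        if not (0.0 < self.global_amr_fraction < 1.0):
            raise ValueError("global_amr_fraction must be in (0, 1)")
        if self.enriched_region is not None:
            chrom, lo, hi, excess = self.enriched_region
            if self.global_amr_fraction + excess > 1.0:
                raise ValueError("excess pushes the enriched frequency above 1")
            if not (0 <= lo < hi):
                raise ValueError("bad enriched region indices")
        if self.tract_rate <= 0:
            raise ValueError("tract_rate must be > 0")


def paper_preset() -> tuple[CohortSpec, dict]:
    """The calibration profile: study design constants plus the four planted

    clock-median pairs (indigenous-role, admixed-role) in years.  Clock sizes
    follow the published convention for each family (71 / 353 / 513 / 1030
    CpGs; the extrinsic blood-composition clock reuses the 71-CpG size).
    """
    spec = CohortSpec(planted_accel_shifts={
        "eeaa_like": (1.26, -2.55),
        "hannum_like": (0.87, -1.67),
        "pheno_like": (1.19, -2.62),
        "grim_like": (0.42, -1.16),
        "horvath_like": (0.0, 0.0),
    })
    clock_plan = {
        "horvath_like": dict(n_cpgs=353, kind="age", transform="horvath"),
        "hannum_like": dict(n_cpgs=71, kind="age", transform="identity"),
        "eeaa_like": dict(n_cpgs=71, kind="age", transform="identity"),
        "pheno_like": dict(n_cpgs=513, kind="age", transform="identity"),
        "grim_like": dict(n_cpgs=1030, kind="age", transform="identity"),
    }
    return spec, clock_plan


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def gen_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample metadata table with exact design counts and truncated-normal ages."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for gi, group in enumerate(("groupA", "groupB")):
        n = spec.n_per_group
        n_f = spec.n_female_per_group
        mu, sd = spec.age_mean_sd[group]
        n_inf = round(spec.infected_fraction * n)
        # infection balanced by sex: same fraction within each sex
        n_inf_f = round(spec.infected_fraction * n_f)
        n_inf_m = n_inf - n_inf_f
        if not (0 <= n_inf_m <= n - n_f):
            raise ValueError("infected count cannot be balanced across sexes")
        rural = min(spec.rural_counts.get(group, 0), n)
        sexes = ["F"] * n_f + ["M"] * (n - n_f)
        infected = ([True] * n_inf_f + [False] * (n_f - n_inf_f)
                    + [True] * n_inf_m + [False] * (n - n_f - n_inf_m))
        paraje = ["rural"] * rural + ["urban"] * (n - rural)
        ages = _truncated_normal(rng, mu, sd, spec.min_age, n)
        cells = rng.dirichlet(_CELL_ALPHA, size=n) if n else np.zeros((0, len(CELL_TYPES)))
        for k in range(n):
            row = {
                "sample_id": f"{'W' if gi == 0 else 'C'}{k + 1:03d}",
                "population": group, "age": float(ages[k]), "sex": sexes[k],
                "infected": infected[k], "paraje": paraje[k],
            }
            for ct, v in zip(CELL_TYPES, cells[k]):
                row[f"cell_{ct}"] = float(v)
            rows.append(row)
    df = pd.DataFrame(rows, columns=(
        ["sample_id", "population", "age", "sex", "infected", "paraje"]
        + [f"cell_{c}" for c in CELL_TYPES]))
    # renormalize cells to kill float round-off in the simplex invariant
    cell_cols = [f"cell_{c}" for c in CELL_TYPES]
    if len(df):
        df[cell_cols] = df[cell_cols].div(df[cell_cols].sum(axis=1), axis=0)
    return validate_sample_table(df)


def _truncated_normal(rng, mu, sd, lo, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu, sd, size=max(n - filled, 8))
        ok = draw[draw >= lo]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def gen_ancestry_props(cohort: pd.DataFrame, amr_mean: float = 0.55,
                       seed: int = 0) -> pd.DataFrame:
    """Attach global ancestry fraction columns (anc_AMR/EUR/AFR/EAS).

    groupA samples are nearly unadmixed (AMR ~ 0.99); groupB samples sit
    around the AMR/EUR admixture mean with small AFR/EAS contributions.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    is_a = (out["population"] == "groupA").to_numpy()
    props = np.empty((n, 4))
    props[is_a] = rng.dirichlet((99.0, 0.5, 0.3, 0.2), size=int(is_a.sum()))
    k = amr_mean * 60.0
    props[~is_a] = rng.dirichlet((k, 60.0 - k - 2.4, 1.8, 0.6), size=int((~is_a).sum()))
    for j, anc in enumerate(("AMR", "EUR", "AFR", "EAS")):
        out[f"anc_{anc}"] = props[:, j]
    return validate_sample_table(out)


# ---------------------------------------------------------------------------
# Clocks and betas
# ---------------------------------------------------------------------------

def _score_bounds(transform: str, adult_age: float) -> tuple[float, float]:
    if transform == "horvath":
        lo = float(age_transform(_AGE_LO, adult_age))
        hi = float(age_transform(_AGE_HI, adult_age))
    else:
        lo, hi = _AGE_LO, _AGE_HI
    return lo, hi


def gen_clock(n_cpgs: int, kind: str = "age", transform: str = "identity",
              seed: int = 0, name: str | None = None,
              adult_age: float = 20.0) -> ClockDefinition:
    """Random linear clock scaled so betas in [0, 1] can represent ages 18-90.

    Coefficients are symmetric around zero; the intercept centers the score
    reachable from betas = 0.5 on the middle of the (transformed) age range,
    and the coefficient scale leaves a safety margin beyond the range ends.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    name = name or f"clock{seed}"
    signs = rng.choice((-1.0, 1.0), size=n_cpgs)
    mags = rng.uniform(0.5, 1.5, size=n_cpgs)
    coef = signs * mags
    lo, hi = _score_bounds(transform, adult_age)
    center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    # max deviation from the betas=0.5 score is 0.5 * sum|coef|
    coef *= (half * _SCALE_MARGIN) / (0.5 * np.abs(coef).sum())
    intercept = center - 0.5 * coef.sum()
    cpgs = [f"cg_{name}_{j:05d}" for j in range(n_cpgs)]
    return ClockDefinition(name=name, kind=kind, intercept=float(intercept),
                           coefficients=pd.Series(coef, index=cpgs),
                           transform=transform, adult_age=adult_age)


def clock_design_betas(clock: ClockDefinition, targets: np.ndarray) -> np.ndarray:
    """Exact inverse design: betas (CpG x sample) whose score equals each target.

    Targets are on the clock's *output* scale (years for age clocks); the
    required linear-predictor deviation from the betas=0.5 baseline is spread
    across CpGs proportionally to coefficient sign, which keeps every beta in
    [0, 1] whenever the target is within the clock's designed range.
    """
    targets = np.asarray(targets, dtype=float)
    score = (age_transform(targets, clock.adult_age)
             if clock.transform == "horvath" else targets)
    coef = clock.coefficients.to_numpy()
    base = clock.intercept + 0.5 * coef.sum()
    half_span = 0.5 * np.abs(coef).sum()
    u = (score - base) / half_span
    if np.any(np.abs(u) > 1.0):
        worst = float(np.max(np.abs(u)))
        raise ValueError(
            f"clock {clock.name!r}: target outside the invertible range "
            f"(|u| = {worst:.3f} > 1); rescale the clock or shrink the planted shift")
    return 0.5 * (1.0 + np.outer(np.sign(coef), u))


def plant_group_medians(ages: np.ndarray, group_a: np.ndarray,
                        median_a: float, median_b: float,
                        sd: float, rng: np.random.Generator,
                        n_iter: int = 60) -> np.ndarray:
    """Shift vector orthogonal to {1, age} with the requested group medians.

    Acceleration residuals are OLS residuals on age, hence mean-zero and
    age-orthogonal by construction; any plantable median pattern must live in
    that subspace.  The construction draws per-group deviations, fixes each
    group's median by order-statistics-preserving adjustments (the skew
    needed for an asymmetric median pair goes into the tails), projects onto
    the orthogonal complement of span{1, age}, and iterates the correction
    until both constraints hold to fine tolerance.
    """
    ages = np.asarray(ages, dtype=float)
    group_a = np.asarray(group_a, dtype=bool)
    n = len(ages)
    basis = np.column_stack([np.ones(n), ages - ages.mean()])
    q, _ = np.linalg.qr(basis)

    def project_out(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    def fix_block(v: np.ndarray, m: float, mean_target: float) -> np.ndarray:
        """Set the block median to m exactly and its mean to mean_target.

        The median is fixed by a constant shift; the mean is then restored by
        moving only the values strictly above (or below) the middle order
        statistics, which preserves the median and the within-block ordering.
        """
        v = v + (m - np.median(v))
        size = len(v)
        delta = mean_target - v.mean()
        if size < 4:
            return v + delta  # tiny blocks: accept the median drift
        order = np.argsort(v, kind="stable")
        half = size // 2
        upper = order[half + 1:]
        lower = order[:half - 1] if size % 2 == 0 else order[:half]
        tail = upper if delta > 0 else lower
        out = v.copy()
        out[tail] += delta * size / len(tail)
        return out

    masks = (group_a, ~group_a)
    medians = (median_a, median_b)
    sizes = tuple(int(m.sum()) for m in masks)
    # overall mean 0 requires a common mean offset t on top of the medians
    t = -sum(s * m for s, m in zip(sizes, medians)) / n
    r = np.empty(n)
    for mask, m, s in zip(masks, medians, sizes):
        dev = rng.normal(0.0, sd, size=s)
        r[mask] = fix_block(dev - np.median(dev) + m, m, m + t)
    for _ in range(n_iter):
        r = project_out(r)
        err = max(abs(m - np.median(r[mask])) for mask, m in zip(masks, medians))
        if err < 1e-9:
            break
        for mask, m in zip(masks, medians):
            r[mask] = fix_block(r[mask], m, m + t)
    return r


def gen_betas(cohort: pd.DataFrame, clocks: list[ClockDefinition],
              spec: CohortSpec | None = None, noise_sd: float = 0.01,
              seed: int = 0, n_background: int = 200) -> pd.DataFrame:
    """CpG x sample beta matrix carrying an age signal through every clock.

    Each clock's per-sample target is chronological age plus a planted
    acceleration shift whose *group medians* equal the values in
    ``spec.planted_accel_shifts`` (zero when the clock is not listed); the
    clock is inverted exactly for that target, then Normal(0, noise_sd) noise
    is added in beta units and values are clipped to [0, 1].  CpGs belonging
    to no clock are Beta(0.5, 0.5) background (the bimodal marginal typical
    of array methylation).
    """
    if not clocks:
        raise ValueError("need at least one clock")
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    ages = cohort["age"].to_numpy(dtype=float)
    group_a = (cohort["population"] == "groupA").to_numpy()
    samples = list(cohort["sample_id"])
    blocks = []
    for clock in clocks:
        planted = spec.planted_accel_shifts.get(clock.name)
        if planted is not None and group_a.any() and (~group_a).any() and len(ages) >= 8:
            shift = plant_group_medians(ages, group_a, planted[0], planted[1],
                                        spec.accel_sd, rng)
        else:
            shift = np.zeros(len(ages))
        if clock.kind == "age":
            targets = ages + shift
        else:  # surrogate level with its own age trend, same designed scale
            targets = 54.0 + 0.8 * (ages - 40.0) + shift
        betas = clock_design_betas(clock, targets)
        blocks.append(pd.DataFrame(betas, index=clock.coefficients.index,
                                   columns=samples))
    if n_background:
        bg = rng.beta(0.5, 0.5, size=(n_background, len(samples)))
        blocks.append(pd.DataFrame(
            bg, index=[f"cg_bg_{j:05d}" for j in range(n_background)],
            columns=samples))
    mat = pd.concat(blocks)
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    return mat.clip(0.0, 1.0)


# ---------------------------------------------------------------------------
# Admixed genotypes, local ancestry and posteriors
# ---------------------------------------------------------------------------

def gen_admixed_genotypes(spec: AdmixtureSpec | None = None, n_samples: int = 48,
                          seed: int = 0, return_posteriors: bool = True):
    """Simulate (GenotypeMatrix, LocalAncestryCalls, posterior table, truth regions).

    Ancestral allele frequencies follow the Balding–Nichols model at the
    given FST; per-haplotype ancestry tracts follow a two-state Markov
    process whose switch probability between adjacent SNPs is
    1 - exp(-tract_rate * d) with d the inter-SNP distance in morgans
    (uniform 1 cM/Mb map) and stationary AMR probability
    ``global_amr_fraction``.  Within the enriched region each haplotype is
    independently forced to AMR with the probability that raises the expected
    AMR frequency there by ``excess``.
    """
    spec = spec or AdmixtureSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    q = spec.global_amr_fraction

    per_chrom = np.full(spec.n_chroms, spec.n_snps // spec.n_chroms)
    per_chrom[:spec.n_snps % spec.n_chroms] += 1
    chroms = [f"chr{c + 1}" for c in range(spec.n_chroms)]

    # Balding–Nichols panels
    p0 = rng.uniform(0.05, 0.95, size=spec.n_snps)
    a = p0 * (1.0 - spec.fst) / spec.fst
    b = (1.0 - p0) * (1.0 - spec.fst) / spec.fst
    freq_amr = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    freq_eur = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)

    # ancestry tracts per chromosome: 1 = AMR, 0 = EUR
    d_morgans = spec.spacing_bp * 1e-8  # 1 cM/Mb
    switch_p = 1.0 - np.exp(-spec.tract_rate * d_morgans)
    anc = np.empty((n_hap, spec.n_snps), dtype=np.int8)
    offset = 0
    for n_c in per_chrom:
        redraw = rng.random((n_hap, n_c)) < switch_p
        redraw[:, 0] = True
        seg = np.maximum.accumulate(
            np.where(redraw, np.arange(n_c)[None, :], 0), axis=1)
        draws = (rng.random((n_hap, n_c)) < q).astype(np.int8)
        anc[:, offset:offset + n_c] = np.take_along_axis(draws, seg, axis=1)
        offset += n_c
    chrom_of = np.repeat(chroms, per_chrom)
    pos = np.concatenate([np.arange(1, n_c + 1) * spec.spacing_bp for n_c in per_chrom])

    truth_rows = []
    if spec.enriched_region is not None:
        chrom, lo, hi, excess = spec.enriched_region
        if chrom not in chroms:
            raise ValueError(f"enriched region chromosome {chrom!r} not simulated")
        sel = np.flatnonzero(chrom_of == chrom)
        if hi > len(sel):
            raise ValueError("enriched region extends past the chromosome")
        region_idx = sel[lo:hi]
        force = rng.random(n_hap) < excess / (1.0 - q)
        anc[np.ix_(force, region_idx)] = 1
        truth_rows.append({"chrom": chrom, "start": int(pos[region_idx[0]]),
                           "end": int(pos[region_idx[-1]]),
                           "start_idx": int(lo), "end_idx": int(hi),
                           "excess": float(excess)})
    truth = pd.DataFrame(truth_rows,
                         columns=["chrom", "start", "end", "start_idx", "end_idx", "excess"])

    # genotypes: haplotype allele ~ Bernoulli(ancestry-specific frequency)
    hap_freq = np.where(anc == 1, freq_amr[None, :], freq_eur[None, :])
    alleles = (rng.random((n_hap, spec.n_snps)) < hap_freq).astype(np.int8)
    dosage = alleles[0::2] + alleles[1::2]

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    haps = [f"{s}_{ab}" for s in samples for ab in ("A", "B")]
    snp_ids = [f"rs{i + 1:06d}" for i in range(spec.n_snps)]
    pair_idx = rng.integers(0, len(_NON_AMBIGUOUS), size=spec.n_snps)
    swap = rng.random(spec.n_snps) < 0.5
    a1 = np.array([_NON_AMBIGUOUS[k][1 if s else 0] for k, s in zip(pair_idx, swap)])
    a2 = np.array([_NON_AMBIGUOUS[k][0 if s else 1] for k, s in zip(pair_idx, swap)])
    snps = pd.DataFrame({"snp": snp_ids, "chrom": chrom_of, "pos": pos,
                         "a1": a1, "a2": a2})
    genotypes = GenotypeMatrix(
        snps, pd.DataFrame(dosage.astype(float), index=samples, columns=snp_ids))

    # posterior confidence and hard calls (UNK where the posterior is <= 0.9)
    conf = rng.random((n_hap, spec.n_snps)) < spec.posterior_confidence
    post_true = np.where(conf, rng.uniform(0.905, 1.0, size=(n_hap, spec.n_snps)),
                         rng.uniform(0.5, 0.9, size=(n_hap, spec.n_snps)))
    labels = np.where(anc == 1, "AMR", "EUR")
    hard = np.where(post_true > 0.9, labels, UNKNOWN_ANCESTRY)
    calls = LocalAncestryCalls(
        snps[["chrom", "pos", "snp"]].copy(),
        pd.DataFrame(hard.T, index=snp_ids, columns=haps))

    posteriors = None
    if return_posteriors:
        n_cells = n_hap * spec.n_snps
        posteriors = pd.DataFrame({
            "chrom": np.tile(chrom_of, n_hap),
            "pos": np.tile(pos, n_hap),
            "snp": np.tile(snp_ids, n_hap),
            "haplotype": np.repeat(haps, spec.n_snps),
            "ancestry": labels.reshape(n_cells),
            "posterior": post_true.reshape(n_cells),
        })
        other = pd.DataFrame({
            "chrom": posteriors["chrom"], "pos": posteriors["pos"],
            "snp": posteriors["snp"], "haplotype": posteriors["haplotype"],
            "ancestry": np.where(posteriors["ancestry"] == "AMR", "EUR", "AMR"),
            "posterior": 1.0 - posteriors["posterior"],
        })
        posteriors = pd.concat([posteriors, other], ignore_index=True)

    return genotypes, calls, posteriors, truth


# ---------------------------------------------------------------------------
# Relatedness and inbreeding
# ---------------------------------------------------------------------------

def gen_relatedness(cohort: pd.DataFrame, n_related_pairs: int = 2,
                    n_inbred: int = 6, seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Kinship table over all pairs plus per-sample inbreeding coefficients.

    Planted related pairs get PiHat in [0.3, 0.6]; all other pairs sit in
    the unrelated band [0, 0.05].  ``n_inbred`` samples (preferring the
    indigenous-role group, whose history motivates the analysis) receive
    inbreeding coefficients in [0.05, 0.15]; the rest are near zero.
    """
    ids = list(cohort["sample_id"])
    n = len(ids)
    max_pairs = n * (n - 1) // 2
    if n_related_pairs > max_pairs:
        raise ValueError(f"cannot plant {n_related_pairs} pairs among {n} samples")
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, k=1)
    pihat = rng.uniform(0.0, 0.05, size=len(ii))
    planted = rng.choice(len(ii), size=n_related_pairs, replace=False) if n_related_pairs else []
    pihat[planted] = rng.uniform(0.3, 0.6, size=n_related_pairs)
    kin = pd.DataFrame({"id1": [ids[i] for i in ii], "id2": [ids[j] for j in jj],
                        "pihat": pihat})
    f = pd.Series(rng.uniform(0.0, 0.01, size=n), index=ids, name="inbreeding_f")
    group_a_ids = [s for s, p in zip(cohort["sample_id"], cohort["population"])
                   if p == "groupA"]
    pool = group_a_ids if len(group_a_ids) >= n_inbred else ids
    inbred = rng.choice(pool, size=min(n_inbred, len(pool)), replace=False)
    f.loc[inbred] = rng.uniform(0.05, 0.15, size=len(inbred))
    return kin, f


# ---------------------------------------------------------------------------
# Mock GWAS catalog
# ---------------------------------------------------------------------------

def gen_gwas_catalog(truth_regions: pd.DataFrame, genotypes: GenotypeMatrix,
                     causal_snp: str, effect: float = 0.29, seed: int = 0,
                     decay_bp: float = 3e5) -> pd.DataFrame:
    """Catalog rows for all SNPs inside the truth regions.

    The causal SNP carries exactly ``effect`` (estimator units per a1
    allele); its neighbours decay exponentially with distance; all other
    SNPs draw a null effect (se times a standard normal) so their Wald
    p-values are uniform.  P-values are the two-sided normal tail of
    effect / se, so catalog statistics are internally consistent.
    """
    from scipy import stats

    snps = genotypes.snps
    if causal_snp not in set(snps["snp"]):
        raise ValueError(f"causal SNP {causal_snp!r} not in the genotype matrix")
    causal = snps[snps["snp"] == causal_snp].iloc[0]
    inside_any = np.zeros(len(snps), dtype=bool)
    causal_inside = False
    for _, reg in truth_regions.iterrows():
        inside = ((snps["chrom"] == reg["chrom"]) & (snps["pos"] >= reg["start"])
                  & (snps["pos"] <= reg["end"])).to_numpy()
        inside_any |= inside
        if reg["chrom"] == causal["chrom"] and reg["start"] <= causal["pos"] <= reg["end"]:
            causal_inside = True
    if not causal_inside:
        raise ValueError(f"causal SNP {causal_snp!r} lies outside every truth region")
    rng = np.random.default_rng(seed)
    rows = snps[inside_any].reset_index(drop=True)
    se = rng.uniform(0.02, 0.05, size=len(rows))
    eff = se * rng.normal(size=len(rows))
    near = (rows["chrom"] == causal["chrom"]).to_numpy()
    dist = np.abs(rows["pos"].to_numpy() - int(causal["pos"]))
    taper = np.exp(-dist / decay_bp)
    strong = near & (taper > 0.05)
    eff[strong] = effect * taper[strong]
    eff[(rows["snp"] == causal_snp).to_numpy()] = effect
    freqs = np.clip(genotypes.dosages[rows["snp"]].mean(axis=0).to_numpy() / 2.0,
                    0.01, 0.99)
    p = 2.0 * stats.norm.sf(np.abs(eff) / se)
    return pd.DataFrame({
        "snp": rows["snp"], "chrom": rows["chrom"], "pos": rows["pos"],
        "a1": rows["a1"], "a2": rows["a2"], "freq_a1": freqs,
        "effect_a1": eff, "se": se, "p": np.clip(p, 1e-300, 1.0),
        "n": rng.integers(30_000, 38_000, size=len(rows)),
    })
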