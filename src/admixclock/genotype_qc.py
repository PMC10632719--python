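"""Genotype quality control: missingness, exact HWE, relatedness, LD pruning.

The filters mirror the standard PLINK-style QC cascade for an array-genotyped
cohort: per-sample call rate (``mind``), per-SNP call rate (``geno``), the
exact Hardy–Weinberg test, identity-by-descent relatedness pruning on the
method-of-moments PiHat, removal of strand-ambiguous A/T and C/G SNPs, and
sliding-window LD pruning on dosage r².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, logger

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class QcReport:
    """Per-filter removal bookkeeping; counts are conserved per axis."""

    n_samples_in: int
    n_snps_in: int
    removed_samples: dict = field(default_factory=dict)   # filter -> list of ids
    removed_snps: dict = field(default_factory=dict)      # filter -> count
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - sum(len(v) for v in self.removed_samples.values())

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - sum(self.removed_snps.values())

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in, "n_snps_in": self.n_snps_in,
            "n_samples_out": self.n_samples_out, "n_snps_out": self.n_snps_out,
            "removed_samples": self.removed_samples,
            "removed_snps": self.removed_snps,
            "params": self.params, "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def filter_missingness(g: GenotypeMatrix, mind: float = 0.05,
                       geno: float = 0.05) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples with missing fraction > ``mind``, then SNPs > ``geno``.

    The order (samples first, then SNPs) follows the usual PLINK convention;
    thresholds are strict (a sample at exactly 5% missing survives mind=0.05).
    """
    if not (0 <= mind <= 1 and 0 <= geno <= 1):
        raise ValueError("mind and geno must be in [0, 1]")
    report = QcReport(g.n_samples, g.n_snps, params={"mind": mind, "geno": geno})
    miss_sample = g.dosages.isna().mean(axis=1)
    keep_samples = miss_sample.index[miss_sample <= mind]
    report.removed_samples["mind"] = sorted(set(g.dosages.index) - set(keep_samples))
    g2 = g.subset(samples=keep_samples)
    miss_snp = g2.dosages.isna().mean(axis=0) if len(keep_samples) else pd.Series(
        1.0, index=g2.dosages.columns)
    keep_snps = list(miss_snp.index[miss_snp <= geno])
    report.removed_snps["geno"] = g2.n_snps - len(keep_snps)
    g3 = g2.subset(snps=keep_snps)
    if g3.n_samples == 0 or g3.n_snps == 0:
        report.warnings.append("matrix empty after missingness filtering")
        logger.warning("missingness filter left an empty matrix")
    return g3, report


# ---------------------------------------------------------------------------
# Exact Hardy–Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided HWE p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table.  Monomorphic SNPs return 1.0 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    # log-probability of each feasible het count (same parity as rare count)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    lg = math.lgamma
    logp = np.array([
        lg(n + 1) - lg(h + 1) - lg(r + 1) - lg(c + 1) + h * math.log(2.0)
        for h, r, c in zip(hets, n_rare_hom, n_common_hom)
    ])
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_ab)]
    # include all tables at most as probable, with slack for float ties
    p = prob[prob <= obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def genotype_counts(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP counts of a1/a1, a1/a2 and a2/a2 genotypes (dosage 2/1/0)."""
    d = g.dosages.to_numpy(dtype=float)
    return pd.DataFrame({
        "n_aa": np.nansum(d == 2.0, axis=0).astype(int),
        "n_ab": np.nansum(d == 1.0, axis=0).astype(int),
        "n_bb": np.nansum(d == 0.0, axis=0).astype(int),
    }, index=g.dosages.columns)


def filter_hwe(g: GenotypeMatrix, p_min: float = 7.00e-08) -> tuple[GenotypeMatrix, pd.Series]:
    """Remove SNPs with exact HWE p below ``p_min``; returns (matrix, p-values)."""
    counts = genotype_counts(g)
    pvals = counts.apply(lambda r: hwe_exact_test(r.n_aa, r.n_ab, r.n_bb)
                         if (r.n_aa + r.n_ab + r.n_bb) > 0 else 1.0, axis=1)
    keep = list(pvals.index[pvals >= p_min])
    return g.subset(snps=keep), pvals


# ---------------------------------------------------------------------------
# Strand-ambiguous SNPs
# ---------------------------------------------------------------------------

def remove_ambiguous(g: GenotypeMatrix) -> GenotypeMatrix:
    """Drop A/T and C/G SNPs, whose strand cannot be resolved when merging."""
    pairs = [frozenset(p) for p in
             zip(g.snps["a1"].to_numpy(), g.snps["a2"].to_numpy())]
    keep = [s for s, p in zip(g.snps["snp"], pairs)
            if set(p) not in AMBIGUOUS_PAIRS]
    return g.subset(snps=keep)


# ---------------------------------------------------------------------------
# IBD / PiHat
# ---------------------------------------------------------------------------

def ibd_pihat(g: GenotypeMatrix, allele_freqs: pd.Series | None = None) -> pd.DataFrame:
    """Method-of-moments PiHat for every sample pair.

    Uses the classic IBS-decomposition estimator: observed genome-wide IBS
    0/1/2 fractions are equated with their expectations given per-SNP a1
    frequencies under IBD states 0/1/2, solved sequentially, clipped to the
    probability simplex.  PiHat = P(IBD=2) + P(IBD=1)/2.  SNPs with frequency
    0 or 1 carry no information and are excluded.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = g.dosages.to_numpy(dtype=float)
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(d, axis=0) / 2.0
    else:
        freqs = allele_freqs.reindex(g.dosages.columns).to_numpy(dtype=float)
    informative = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    if not informative.any():
        raise ValueError("no informative SNPs for IBD estimation")
    p = freqs[informative]
    q = 1.0 - p
    d = d[:, informative]
    # expectations of IBS state given IBD state, averaged over SNPs
    e0_ibd0 = np.mean(2 * p**2 * q**2)
    e1_ibd0 = np.mean(4 * p**3 * q + 4 * p * q**3)
    e2_ibd0 = np.mean(p**4 + q**4 + 4 * p**2 * q**2)
    e1_ibd1 = np.mean(2 * p * q)
    e2_ibd1 = np.mean(p**2 + q**2)
    samples = list(g.dosages.index)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            both = np.isfinite(d[i]) & np.isfinite(d[j])
            if not both.any():
                continue
            diff = np.abs(d[i, both] - d[j, both])
            # dosage difference 2 <=> IBS0; 1 <=> IBS1; 0 <=> IBS2 except
            # double-het pairs (both dosage 1) are always IBS2
            obs0 = np.mean(diff == 2.0)
            obs1 = np.mean(diff == 1.0)
            obs2 = np.mean(diff == 0.0)
            p0 = obs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
            p1 = (obs1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
            p2 = obs2 - p0 * e2_ibd0 - p1 * e2_ibd1
            probs = np.clip([p0, p1, p2], 0.0, None)
            total = probs.sum()
            probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
            rows.append((samples[i], samples[j], probs[2] + probs[1] / 2.0))
    return pd.DataFrame(rows, columns=["id1", "id2", "pihat"])


def filter_related(g: GenotypeMatrix, kin: pd.DataFrame,
                   threshold: float = 0.25) -> tuple[GenotypeMatrix, list[str]]:
    """Greedily remove one member of every pair with PiHat above ``threshold``.

    While any offending pair remains, the member with the higher missingness
    is removed (ties broken by lexicographically larger id).
    """
    miss = g.dosages.isna().mean(axis=1)
    present = set(g.dosages.index)
    pairs = [(r.id1, r.id2) for r in kin.itertuples()
             if r.pihat > threshold and r.id1 in present and r.id2 in present]
    removed: list[str] = []
    active = set(present)
    while True:
        live = [(a, b) for a, b in pairs if a in active and b in active]
        if not live:
            break
        a, b = live[0]
        drop = max((miss.get(a, 0.0), a), (miss.get(b, 0.0), b))[1]
        active.discard(drop)
        removed.append(drop)
    keep = [s for s in g.dosages.index if s in active]
    return g.subset(samples=keep), sorted(removed)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Squared dosage correlation between SNP columns, NaN-tolerant."""
    with np.errstate(invalid="ignore", divide="ignore"):
        df = pd.DataFrame(d)
        r = df.corr().to_numpy()
    return r**2


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> list[str]:
    """Sliding-window LD pruning on composite (dosage) r²; returns kept SNP ids.

    Within each window of ``window`` SNPs (advancing by ``step``), pairs with
    r² above ``r2_max`` repeatedly lose their later-positioned member.
    Pruning is carried out independently per chromosome, so the result does
    not depend on chromosome processing order.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    kept: list[str] = []
    for chrom, sub in g.snps.groupby("chrom", sort=False):
        ids = list(sub["snp"])
        d = g.dosages[ids].to_numpy(dtype=float)
        alive = np.ones(len(ids), dtype=bool)
        # repeat the sliding scan until a full pass removes nothing, so the
        # kept set is a fixpoint (pruning a pruned panel is the identity)
        stable = False
        while not stable:
            stable = True
            live_idx = np.flatnonzero(alive)
            start = 0
            while start < len(live_idx):
                idx = list(live_idx[start:start + window])
                changed = True
                while changed and len(idx) > 1:
                    changed = False
                    r2 = _pairwise_r2(d[:, idx])
                    for a in range(len(idx)):
                        for b in range(a + 1, len(idx)):
                            if np.isfinite(r2[a, b]) and r2[a, b] > r2_max:
                                alive[idx[b]] = False
                                idx.pop(b)
                                changed = True
                                stable = False
                                break
                        if changed:
                            break
                if start + window >= len(live_idx):
                    break
                start += step
        kept.extend([s for s, a in zip(ids, alive) if a])
    return kept


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def run_qc(g: GenotypeMatrix, mind: float = 0.05, geno: float = 0.05,
           hwe_p: float = 7.00e-08, pihat_max: float = 0.25,
           kin: pd.DataFrame | None = None,
           ld_window: int = 50, ld_step: int = 5, ld_r2_max: float = 0.2,
           ) -> tuple[GenotypeMatrix, list[str], QcReport]:
    """Full QC cascade; returns (filtered matrix, LD-pruned SNP list, report)."""
    g1, report = filter_missingness(g, mind=mind, geno=geno)
    report.params.update({"hwe_p": hwe_p, "pihat_max": pihat_max,
                          "ld_window": ld_window, "ld_step": ld_step,
                          "ld_r2_max": ld_r2_max})
    g2, _ = filter_hwe(g1, p_min=hwe_p)
    report.removed_snps["hwe"] = g1.n_snps - g2.n_snps
    if kin is None and g2.n_samples >= 2 and g2.n_snps >= 1:
        kin = ibd_pihat(g2)
    if kin is not None:
        g3, removed = filter_related(g2, kin, threshold=pihat_max)
        report.removed_samples["relatedness"] = removed
    else:
        g3 = g2
        report.removed_samples["relatedness"] = []
    g4 = remove_ambiguous(g3)
    report.removed_snps["ambiguous"] = g3.n_snps - g4.n_snps
    kept = ld_prune(g4, window=ld_window, step=ld_step, r2_max=ld_r2_max)
    report.params["ld_kept"] = len(kept)
    return g4, kept, report
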