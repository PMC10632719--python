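"""Local-ancestry deviation scan (admixture mapping) and global-ancestry tests.

Given per-haplotype local-ancestry assignments, the scan computes the
per-SNP frequency ``f_anc`` of a chosen ancestry, standardizes it against
the genome-wide mean and standard deviation,

    Z_anc = (f_anc - mu_anc) / sigma_anc,

converts Z to two-sided normal p-values, and calls regions as maximal runs
of consecutive same-signed SNPs with |Z| above a threshold.  Haplotypes
whose ancestry could not be confidently assigned (label ``UNK``) are
excluded from the frequency denominator by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (ANCESTRIES, UNKNOWN_ANCESTRY, LocalAncestryCalls,
                         SchemaError, logger)
from .group_comparison import bh_adjust, normality_gate


@dataclass
class AncestryScanResult:
    """Per-SNP scan table plus genome-wide moments and called regions."""

    ancestry: str
    snp_table: pd.DataFrame        # chrom, pos, snp, f_anc, z, p (masked SNPs absent)
    mu: float
    sigma: float
    regions: pd.DataFrame          # chrom, start, end, n_snps, z_max, p_min, direction
    n_masked: int = 0
    extra: dict = field(default_factory=dict)


def collapse_posteriors(post: pd.DataFrame, threshold: float = 0.9) -> LocalAncestryCalls:
    """Hard-call ancestries from a long posterior table.

    A haplotype/SNP cell is assigned the argmax ancestry only when its
    posterior strictly exceeds ``threshold``; otherwise the label is ``UNK``.
    Posteriors for each (haplotype, SNP) must form a simplex.
    """
    sums = post.groupby(["snp", "haplotype"], sort=False)["posterior"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        snp, hap = bad.index[0]
        raise SchemaError(
            f"posteriors do not sum to 1 at snp {snp!r}, haplotype {hap!r}: {bad.iloc[0]:.6f}")
    wide = post.pivot_table(index="snp", columns="haplotype", values="posterior",
                            aggfunc="max", sort=False)
    best = post.loc[post.groupby(["snp", "haplotype"], sort=False)["posterior"].idxmax()]
    labels = best.pivot(index="snp", columns="haplotype", values="ancestry")
    calls = labels.where(wide > threshold, UNKNOWN_ANCESTRY)
    snp_meta = post[["chrom", "pos", "snp"]].drop_duplicates("snp").reset_index(drop=True)
    calls = calls.reindex(snp_meta["snp"])
    calls.index.name = None
    calls.columns.name = None
    # preserve the haplotype order of first appearance
    hap_order = list(dict.fromkeys(post["haplotype"]))
    return LocalAncestryCalls(snp_meta, calls[hap_order])


def ancestry_frequency(calls: LocalAncestryCalls, anc: str) -> pd.Series:
    """Per-SNP frequency of ``anc`` among non-UNK haplotypes (NaN when all UNK)."""
    if anc not in ANCESTRIES:
        raise ValueError(f"unknown ancestry {anc!r}")
    arr = calls.calls.to_numpy()
    known = (arr != UNKNOWN_ANCESTRY).sum(axis=1)
    hits = (arr == anc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(known > 0, hits / np.maximum(known, 1), np.nan)
    n_masked = int((known == 0).sum())
    if n_masked:
        logger.warning("%d SNPs masked (all haplotypes UNK)", n_masked)
    return pd.Series(f, index=calls.calls.index, name=f"f_{anc}")


def zscan(f: pd.Series) -> pd.DataFrame:
    """Standardize per-SNP ancestry frequencies genome-wide.

    mu and sigma are the mean and sample SD (ddof=1) over unmasked SNPs;
    p is the two-sided normal tail probability.  Masked (NaN) SNPs are
    dropped from the output.
    """
    valid = f.dropna()
    if len(valid) < 2:
        raise ValueError("zscan needs at least 2 unmasked SNPs")
    mu = float(valid.mean())
    sigma = float(valid.std(ddof=1))
    if sigma == 0:
        raise ValueError("no ancestry variance across SNPs")
    z = (valid - mu) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"f_anc": valid, "z": z, "p": p})
    out.attrs["mu"] = mu
    out.attrs["sigma"] = sigma
    return out


def call_regions(scan: pd.DataFrame, snps: pd.DataFrame, z_threshold: float = 3.0,
                 min_snps: int = 2) -> pd.DataFrame:
    """Maximal runs of consecutive same-signed SNPs with |z| above threshold.

    ``scan`` is indexed by SNP id (from :func:`zscan`); ``snps`` supplies
    chrom/pos.  Region bounds are the first and last member SNP positions
    (1-based inclusive).  ``z_max`` is the member z of largest magnitude,
    signed; direction is 'over' for positive z runs, 'under' for negative.
    """
    meta = snps.set_index("snp").loc[scan.index]
    rows = []
    for chrom in meta["chrom"].unique():
        sel = meta["chrom"] == chrom
        sub = scan[sel.to_numpy()]
        pos = meta.loc[sel, "pos"].to_numpy()
        z = sub["z"].to_numpy()
        sig = np.abs(z) > z_threshold
        sign = np.sign(z)
        start = None
        for i in range(len(z) + 1):
            open_run = start is not None
            extend = (i < len(z) and sig[i] and open_run and sign[i] == sign[start])
            if extend:
                continue
            if open_run:
                length = i - start
                if length >= min_snps:
                    zz = z[start:i]
                    pp = sub["p"].to_numpy()[start:i]
                    kmax = int(np.argmax(np.abs(zz)))
                    rows.append({
                        "chrom": chrom, "start": int(pos[start]), "end": int(pos[i - 1]),
                        "n_snps": int(length), "z_max": float(zz[kmax]),
                        "p_min": float(pp.min()),
                        "direction": "over" if zz[kmax] > 0 else "under",
                    })
                start = None
            if i < len(z) and sig[i]:
                start = i
    cols = ["chrom", "start", "end", "n_snps", "z_max", "p_min", "direction"]
    return pd.DataFrame(rows, columns=cols)


def scan_ancestry(calls: LocalAncestryCalls, anc: str = "AMR",
                  z_threshold: float = 3.0, min_snps: int = 2,
                  exclude_outliers: bool = False) -> AncestryScanResult:
    """End-to-end deviation scan for one ancestry.

    ``exclude_outliers`` optionally drops samples whose global fraction of
    ``anc`` is more than 3 SD from the cohort mean before computing
    frequencies (both haplotypes of the sample are removed).
    """
    if exclude_outliers:
        arr = calls.calls.to_numpy()
        hap_frac = pd.Series((arr == anc).mean(axis=0), index=calls.calls.columns)
        samp_frac = hap_frac.groupby(
            hap_frac.index.to_series().str.rsplit("_", n=1).str[0]).mean()
        zed = (samp_frac - samp_frac.mean()) / samp_frac.std(ddof=1)
        drop = set(zed.index[zed.abs() > 3])
        if drop:
            logger.info("excluding ancestry-extreme samples: %s", sorted(drop))
            keep = [h for h in calls.calls.columns if h.rsplit("_", 1)[0] not in drop]
            calls = LocalAncestryCalls(calls.snps, calls.calls[keep])
    f = ancestry_frequency(calls, anc)
    scan = zscan(f)
    regions = call_regions(scan, calls.snps, z_threshold=z_threshold, min_snps=min_snps)
    table = calls.snps.set_index("snp").join(scan, how="inner")
    table.index.name = "snp"
    table = table.reset_index()[["chrom", "pos", "snp", "f_anc", "z", "p"]]
    return AncestryScanResult(
        ancestry=anc, snp_table=table, mu=scan.attrs["mu"], sigma=scan.attrs["sigma"],
        regions=regions, n_masked=int(f.isna().sum()))


def global_ancestry_correlation(props: pd.DataFrame, est: pd.DataFrame,
                                shapiro_alpha: float = 0.05,
                                fdr_q: float | None = None) -> pd.DataFrame:
    """Correlate per-sample global ancestry fractions with every estimator.

    Pearson when both variables pass the Shapiro–Wilk gate, Kendall
    otherwise; constant columns are skipped with a note.  An optional BH
    q column is added when ``fdr_q`` is given.
    """
    common = props.index.intersection(est.index)
    if len(common) < 4:
        raise ValueError("need at least 4 complete sample pairs")
    rows = []
    for anc_col in props.columns:
        x = props.loc[common, anc_col].to_numpy(dtype=float)
        for est_col in est.columns:
            y = est.loc[common, est_col].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("skipping constant column pair (%s, %s)", anc_col, est_col)
                continue
            both_normal = (normality_gate(x, shapiro_alpha) == "normal"
                           and normality_gate(y, shapiro_alpha) == "normal")
            if both_normal:
                r, p = stats.pearsonr(x, y)
                method = "pearson"
            else:
                r, p = stats.kendalltau(x, y)
                method = "kendall"
            rows.append({"ancestry": anc_col, "estimator": est_col,
                         "r": float(r), "p": float(p), "method": method})
    out = pd.DataFrame(rows)
    if fdr_q is not None and len(out):
        qvals, flags = bh_adjust(out["p"].to_numpy(), q=fdr_q)
        out["bh_q"] = qvals
        out["significant"] = flags
    return out
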