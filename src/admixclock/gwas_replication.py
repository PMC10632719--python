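"""Discovery/replication of estimator-associated SNPs in ancestry-deviant regions.

Discovery intersects an external GWAS-catalog table with the regions called
by the local-ancestry scan and keeps catalog hits below a nominal p cutoff.
Replication re-orients each candidate's dosage to count the ancestry-enriched
allele and fits a per-SNP OLS of the estimator on dosage in the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, logger


@dataclass
class ReplicationResult:
    snp: str
    enriched_allele: str
    catalog_effect_aligned: float
    beta: float
    se: float
    nominal_p: float
    replicated: bool
    direction_consistent: bool


def discover(regions: pd.DataFrame, catalog: pd.DataFrame,
             p_max: float = 0.01) -> pd.DataFrame:
    """Catalog SNPs inside any called region with catalog p below ``p_max``.

    Regions and catalog must share the chromosome naming convention; bounds
    are 1-based inclusive.  Each hit is annotated with the region index and
    the region's deviation direction.
    """
    if len(regions) == 0 or len(catalog) == 0:
        return catalog.iloc[0:0].assign(region_id=pd.Series(dtype=int),
                                        region_direction=pd.Series(dtype=str))
    reg_chroms = set(regions["chrom"])
    cat_chroms = set(catalog["chrom"])
    if not reg_chroms & cat_chroms:
        raise ValueError(
            f"no shared chromosome names between regions {sorted(reg_chroms)} "
            f"and catalog {sorted(cat_chroms)}")
    rows = []
    for _, snp in catalog.iterrows():
        if snp["p"] >= p_max:
            continue
        for rid, reg in regions.iterrows():
            if (snp["chrom"] == reg["chrom"]
                    and reg["start"] <= snp["pos"] <= reg["end"]):
                rec = snp.to_dict()
                rec["region_id"] = rid
                rec["region_direction"] = reg["direction"]
                rows.append(rec)
                break
    cols = list(catalog.columns) + ["region_id", "region_direction"]
    return pd.DataFrame(rows, columns=cols)


def align_alleles(candidate: pd.Series, genotypes: GenotypeMatrix,
                  enriched_allele: str) -> tuple[pd.Series, float] | None:
    """Re-orient a candidate SNP's dosage to count the enriched allele.

    Returns (oriented dosage, aligned catalog effect) or None when the SNP is
    absent or the allele sets disagree (no strand flipping is attempted —
    ambiguous SNPs are removed upstream).
    """
    snp_id = candidate["snp"]
    match = genotypes.snps[genotypes.snps["snp"] == snp_id]
    if len(match) == 0:
        logger.warning("candidate %s absent from genotype matrix", snp_id)
        return None
    rec = match.iloc[0]
    cohort_alleles = {rec["a1"], rec["a2"]}
    catalog_alleles = {candidate["a1"], candidate["a2"]}
    if cohort_alleles != catalog_alleles or enriched_allele not in cohort_alleles:
        logger.warning("allele mismatch for %s: cohort %s vs catalog %s (enriched %s)",
                       snp_id, cohort_alleles, catalog_alleles, enriched_allele)
        return None
    dosage = genotypes.dosages[snp_id]
    if rec["a1"] != enriched_allele:
        dosage = 2.0 - dosage
    effect = float(candidate["effect_a1"])
    if candidate["a1"] != enriched_allele:
        effect = -effect
    return dosage.rename(snp_id), effect


def _ols_slope(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """Slope of the first column of X in OLS with intercept; (beta, se, p)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - design.shape[1]
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2.0 * stats.t.sf(abs(beta) / se, dof)) if se > 0 else 0.0
    return beta, se, p


def replicate(genotypes: GenotypeMatrix, est_column: pd.Series,
              candidates: pd.DataFrame, alpha: float = 0.01,
              covariates: pd.DataFrame | None = None,
              enriched_alleles: pd.Series | None = None) -> pd.DataFrame:
    """Per-SNP in-cohort association of the estimator with oriented dosage.

    ``enriched_alleles`` maps snp id -> ancestry-enriched allele; when absent,
    the catalog a1 is used as the orientation allele.  Monomorphic SNPs in
    the cohort are skipped with a note.
    """
    results: list[ReplicationResult] = []
    for _, cand in candidates.iterrows():
        allele = (str(enriched_alleles[cand["snp"]])
                  if enriched_alleles is not None and cand["snp"] in enriched_alleles
                  else str(cand["a1"]))
        aligned = align_alleles(cand, genotypes, allele)
        if aligned is None:
            continue
        dosage, cat_effect = aligned
        common = est_column.index.intersection(dosage.index)
        y = est_column.loc[common].to_numpy(dtype=float)
        d = dosage.loc[common].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(d)
        y, d = y[ok], d[ok]
        if len(y) < 10:
            raise ValueError(f"replication needs n >= 10 (got {len(y)} for {cand['snp']})")
        if np.ptp(d) == 0:
            logger.warning("skipping monomorphic SNP %s", cand["snp"])
            continue
        X = d[:, None]
        if covariates is not None:
            X = np.column_stack([X, covariates.loc[common].to_numpy(dtype=float)[ok]])
        beta, se, p = _ols_slope(y, X)
        results.append(ReplicationResult(
            snp=str(cand["snp"]), enriched_allele=allele,
            catalog_effect_aligned=cat_effect, beta=beta, se=se, nominal_p=p,
            replicated=bool(p < alpha),
            direction_consistent=bool(np.sign(beta) == np.sign(cat_effect))))
    return pd.DataFrame([r.__dict__ for r in results])


def ld_groups(genotypes: GenotypeMatrix, snp_ids: list[str],
              r2_min: float = 0.8) -> list[list[str]]:
    """Cluster replicated SNPs sharing an LD area (pairwise dosage r² >= r2_min)."""
    import networkx as nx

    present = [s for s in snp_ids if s in set(genotypes.snps["snp"])]
    graph = nx.Graph()
    graph.add_nodes_from(present)
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            r = genotypes.dosages[[a, b]].corr().iloc[0, 1]
            if np.isfinite(r) and r**2 >= r2_min:
                graph.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: present.index(c[0]))
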