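"""Inter-population tests on the estimator table.

The comparison procedure is normality-gated: each estimator is tested with
Shapiro–Wilk in both groups, and the headline p comes from a Welch t-test
when both pass (p >= alpha in both) or a two-sided Mann–Whitney test
otherwise.  Both tests are always computed and reported for transparency.
P-values across estimators are corrected by Benjamini–Hochberg step-up, and
estimators are grouped into independent clusters by the Spearman-correlation
graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    estimator: str
    test_used: str          # "t" | "wilcoxon"
    statistic: float
    nominal_p: float
    t_p: float
    wilcoxon_p: float
    median_a: float
    median_b: float
    bh_q: float = np.nan
    significant: bool = False


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> str:
    """Shapiro–Wilk gate for one sample: 'normal' or 'non-normal'.

    Degenerate (constant) samples cannot be normal and are classified
    'non-normal' by convention.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("normality gate needs n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro–Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        return "non-normal"
    _, p = stats.shapiro(x)
    return "normal" if p >= alpha else "non-normal"


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact when both n <= 10 and no ties."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(values: pd.Series, groups: pd.Series,
                   shapiro_alpha: float = 0.05) -> ComparisonResult:
    """Gated two-group comparison of one estimator column."""
    values, groups = values.align(groups, join="inner")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a = values[groups == labels[0]].to_numpy(dtype=float)
    b = values[groups == labels[1]].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    gate = (normality_gate(a, shapiro_alpha) == "normal"
            and normality_gate(b, shapiro_alpha) == "normal")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    u_stat, u_p = _mannwhitney_p(a, b)
    test_used = "t" if gate else "wilcoxon"
    stat, p = (float(t_stat), float(t_p)) if gate else (u_stat, u_p)
    return ComparisonResult(
        estimator=str(values.name), test_used=test_used, statistic=stat,
        nominal_p=p, t_p=float(t_p), wilcoxon_p=u_p,
        median_a=float(np.median(a)), median_b=float(np.median(b)))


def bh_adjust(pvals, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up q-values and q <= threshold flags."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must be in [0, 1]")
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return qvals, qvals <= q


def compare_all(est: pd.DataFrame, groups: pd.Series, fdr_q: float = 0.1,
                shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Run the gated comparison for every estimator column, with BH FDR."""
    results = [compare_groups(est[c], groups, shapiro_alpha) for c in est.columns]
    qvals, flags = bh_adjust([r.nominal_p for r in results], q=fdr_q)
    for r, qv, fl in zip(results, qvals, flags):
        r.bh_q = float(qv)
        r.significant = bool(fl)
    return pd.DataFrame([r.__dict__ for r in results])


def independence_groups(est: pd.DataFrame, alpha: float = 0.01) -> list[list[str]]:
    """Clusters of mutually dependent estimators.

    Two estimators are connected when their Spearman correlation differs
    significantly from zero (p < alpha); clusters are the connected
    components, so the number of clusters is the number of independent
    signals in the table.
    """
    cols = list(est.columns)
    if len(cols) < 2:
        return [[c] for c in cols]
    graph = nx.Graph()
    graph.add_nodes_from(cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            rho, p = stats.spearmanr(est[ci], est[cj])
            if np.isfinite(p) and p < alpha:
                graph.add_edge(ci, cj)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: cols.index(c[0]))


def median_discrepancy(est: pd.DataFrame, groups: pd.Series,
                       clock_subset: list[str] | None = None) -> pd.DataFrame:
    """Per-group medians of the acceleration columns (clock subset optional)."""
    cols = clock_subset if clock_subset is not None else list(est.columns)
    missing = [c for c in cols if c not in est.columns]
    if missing:
        raise KeyError(f"estimator columns not present: {missing}")
    groups = groups.loc[est.index]
    return est[cols].groupby(groups).median()
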