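"""Relatedness and inbreeding associations with epigenetic estimators.

The pairwise *delta* statistic is the absolute difference between two
individuals' estimator values; if relatedness constrains the epigenetic
signal, higher-PiHat pairs should show smaller deltas.  Because the
n(n-1)/2 pairs are not independent, a label-permutation p-value (permuting
individuals and recomputing all deltas) is reported alongside the naive
pair-level correlation and is the recommended inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .group_comparison import bh_adjust, normality_gate


def pairwise_delta(est: pd.DataFrame) -> pd.DataFrame:
    """All unordered sample pairs with |e_i - e_j| per estimator column."""
    if len(est) < 2:
        raise ValueError("need at least 2 samples")
    ids = list(est.index)
    ii, jj = np.triu_indices(len(ids), k=1)
    vals = est.to_numpy(dtype=float)
    out = pd.DataFrame({
        "id1": [ids[i] for i in ii],
        "id2": [ids[j] for j in jj],
    })
    for k, col in enumerate(est.columns):
        out[col] = np.abs(vals[ii, k] - vals[jj, k])
    return out


def _pair_key(df: pd.DataFrame) -> pd.Index:
    a = df[["id1", "id2"]].astype(str)
    return pd.Index(np.where(a["id1"] < a["id2"],
                             a["id1"] + "|" + a["id2"],
                             a["id2"] + "|" + a["id1"]))


def _gated_corr(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    normal = (normality_gate(x, alpha) == "normal"
              and normality_gate(y, alpha) == "normal")
    if normal:
        r, p = stats.pearsonr(x, y)
        return float(r), float(p), "pearson"
    r, p = stats.kendalltau(x, y)
    return float(r), float(p), "kendall"


def kinship_delta_association(est: pd.DataFrame, kin: pd.DataFrame,
                              n_permutations: int = 999,
                              seed: int = 0,
                              shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Correlate PiHat with the per-estimator delta over overlapping pairs.

    Reports the gated Pearson/Kendall correlation with its nominal p, plus a
    permutation p obtained by permuting individual labels (not pairs) and
    recomputing the full delta table, which respects the dependence among
    pairs sharing an individual.
    """
    deltas = pairwise_delta(est)
    kin = kin.copy()
    kin.index = _pair_key(kin)
    deltas.index = _pair_key(deltas)
    common = deltas.index.intersection(kin.index)
    if len(common) < 4:
        raise ValueError("need at least 4 overlapping pairs")
    pihat = kin.loc[common, "pihat"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = len(est)
    rows = []
    for col in est.columns:
        d = deltas.loc[common, col].to_numpy(dtype=float)
        r, p, method = _gated_corr(pihat, d, shapiro_alpha)
        # permutation null: shuffle individuals, rebuild deltas, recorrelate
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            est_perm = pd.DataFrame({col: est[col].to_numpy()[perm]}, index=est.index)
            d_perm = pairwise_delta(est_perm)
            d_perm.index = _pair_key(d_perm)
            dp = d_perm.loc[common, col].to_numpy(dtype=float)
            if method == "pearson":
                r_perm = stats.pearsonr(pihat, dp)[0]
            else:
                r_perm = stats.kendalltau(pihat, dp)[0]
            if abs(r_perm) >= abs(r):
                exceed += 1
        perm_p = (exceed + 1) / (n_permutations + 1)
        rows.append({"estimator": col, "r": r, "nominal_p": p,
                     "method": method, "permutation_p": perm_p,
                     "n_pairs": len(common)})
    return pd.DataFrame(rows)


def inbreeding_association(f: pd.Series, est: pd.DataFrame,
                           fdr_q: float = 0.01) -> pd.DataFrame:
    """Pearson and Kendall association of the inbreeding coefficient with each

    estimator, BH-corrected across estimators (significance at q < ``fdr_q``,
    applied to the Pearson p by convention; the Kendall p is reported too).
    """
    common = f.index.intersection(est.index)
    f_vals = f.loc[common].to_numpy(dtype=float)
    if len(common) < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(f_vals) == 0:
        raise ValueError("constant inbreeding coefficient")
    rows = []
    for col in est.columns:
        y = est.loc[common, col].to_numpy(dtype=float)
        pr, pp = stats.pearsonr(f_vals, y)
        kr, kp = stats.kendalltau(f_vals, y)
        rows.append({"estimator": col, "pearson_r": float(pr), "p_pearson": float(pp),
                     "kendall_tau": float(kr), "p_kendall": float(kp)})
    out = pd.DataFrame(rows)
    qvals, flags = bh_adjust(out["p_pearson"].to_numpy(), q=fdr_q)
    out["fdr_q"] = qvals
    out["significant"] = flags
    return out
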