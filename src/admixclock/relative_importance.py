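"""LMG (Shapley) decomposition of linear-model R² across predictors.

The LMG statistic attributes to each predictor its average sequential R²
gain over all orderings of predictor entry — equivalently a Shapley value
with subset weights w(s) = s!(p-s-1)!/p!.  The implementation enumerates
all 2^p predictor subsets exactly (the model configurations used here have
p <= 4), computes each subset's centered R² by OLS, and combines gains with
the closed-form weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

MAX_PREDICTORS = 15  # exact 2^p enumeration bound


@dataclass
class LmgResult:
    model: str
    predictors: list[str]
    r2_full: float
    lmg_raw: pd.Series       # sums to r2_full
    lmg_norm: pd.Series      # sums to 1
    top_predictor: str
    pct_total_variance: float  # lmg_norm[top] * r2_full


def _r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """Centered R² of OLS with intercept (0.0 for the empty model)."""
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("outcome has zero variance")
    if X is None or X.shape[1] == 0:
        return 0.0
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return 1.0 - float(resid @ resid) / tss


def lmg(y, X: pd.DataFrame, model: str = "model") -> LmgResult:
    """Exact LMG decomposition of R² for outcome ``y`` on predictors ``X``.

    Raises for constant predictors, near-collinear designs, too few samples
    (need n > p + 1) or p above the exact-enumeration bound.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    n, p = Xa.shape
    if p > MAX_PREDICTORS:
        raise ValueError(f"p = {p} exceeds exact enumeration bound {MAX_PREDICTORS}")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    const = [names[j] for j in range(p) if np.ptp(Xa[:, j]) == 0]
    if const:
        raise ValueError(f"constant predictors: {const}")
    # collinearity guard on the standardized design
    Xs = (Xa - Xa.mean(axis=0)) / Xa.std(axis=0, ddof=1)
    sv = np.linalg.svd(Xs, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        corr = np.corrcoef(Xa, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"near-collinear design; most correlated pair: {names[i]}, {names[j]}")

    r2_cache: dict[frozenset, float] = {}
    def subset_r2(s: tuple) -> float:
        key = frozenset(s)
        if key not in r2_cache:
            r2_cache[key] = _r2(y, Xa[:, list(s)] if s else None)
        return r2_cache[key]

    shares = np.zeros(p)
    idx = list(range(p))
    for k in idx:
        others = [j for j in idx if j != k]
        total = 0.0
        for size in range(p):
            w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for s in combinations(others, size):
                total += w * (subset_r2(s + (k,)) - subset_r2(s))
        shares[k] = total
    r2_full = subset_r2(tuple(idx))
    if np.any(shares < -1e-12):
        raise ValueError(f"negative LMG share beyond numerical floor: {shares.min():.3e}")
    shares = np.clip(shares, 0.0, None)
    raw = pd.Series(shares, index=names)
    norm = raw / raw.sum() if raw.sum() > 0 else raw * 0.0
    top = str(norm.idxmax())
    return LmgResult(model=model, predictors=names, r2_full=r2_full,
                     lmg_raw=raw, lmg_norm=norm, top_predictor=top,
                     pct_total_variance=float(norm[top] * r2_full))


# ---------------------------------------------------------------------------
# The three model configurations
# ---------------------------------------------------------------------------

def build_model_frames(metadata: pd.DataFrame, est: pd.DataFrame) -> dict[str, dict]:
    """Design frames for the joint, indigenous-only and admixed-only models.

    Encodings: Pop = 1 for groupA (the indigenous-role population); Female =
    1 for females; T.cruzi = 1 for infected; Paraje = 1 for urban residence;
    Inbreed = inbreeding coefficient; EUR / AMR = global ancestry fractions.
    Returns ``{model: {"X": DataFrame, "samples": index}}``; each estimator
    column of ``est`` restricted to those samples is the outcome.
    """
    meta = metadata.set_index("sample_id")
    meta = meta.loc[meta.index.intersection(est.index)]
    frames: dict[str, dict] = {}

    joint = pd.DataFrame({
        "Pop": (meta["population"] == "groupA").astype(float),
        "Female": (meta["sex"] == "F").astype(float),
        "T.cruzi": meta["infected"].astype(float),
    })
    frames["joint"] = {"X": joint, "samples": joint.index}

    grpA = meta[meta["population"] == "groupA"]
    if "inbreeding_f" not in grpA.columns or grpA["inbreeding_f"].isna().all():
        raise KeyError("groupA model requires an 'inbreeding_f' metadata column")
    xa = pd.DataFrame({
        "Inbreed": grpA["inbreeding_f"].astype(float),
        "Paraje": (grpA["paraje"] == "urban").astype(float),
        "Female": (grpA["sex"] == "F").astype(float),
        "T.cruzi": grpA["infected"].astype(float),
    })
    frames["groupA"] = {"X": xa, "samples": xa.index}

    grpB = meta[meta["population"] == "groupB"]
    for col in ("anc_EUR", "anc_AMR"):
        if col not in grpB.columns:
            raise KeyError(f"groupB model requires metadata column {col!r}")
    xb = pd.DataFrame({
        "EUR": grpB["anc_EUR"].astype(float),
        "AMR": grpB["anc_AMR"].astype(float),
        "Female": (grpB["sex"] == "F").astype(float),
        "T.cruzi": grpB["infected"].astype(float),
    })
    corr = xb[["EUR", "AMR"]].corr().iloc[0, 1]
    if np.isfinite(corr) and abs(corr) > 0.999:
        sv = np.linalg.svd((xb - xb.mean()).to_numpy(), compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise ValueError(
            f"EUR and AMR are collinear (r={corr:.4f}, condition number {cond:.1f}); "
            "drop one or add minor-ancestry variation")
    frames["groupB"] = {"X": xb, "samples": xb.index}
    return frames


def importance_report(frames: dict[str, dict], est: pd.DataFrame) -> pd.DataFrame:
    """Per-(model, estimator) LMG attribution in long form.

    Columns: model, estimator, predictor, lmg_raw, lmg_norm, r2_full,
    is_top, pct_total_variance; fit failures yield NA rows with the reason.
    """
    rows = []
    for model, spec in frames.items():
        X = spec["X"]
        samples = spec["samples"]
        for col in est.columns:
            y = est.loc[est.index.intersection(samples), col]
            Xy = X.loc[y.index]
            try:
                res = lmg(y.to_numpy(), Xy, model=model)
            except ValueError as exc:
                rows.append({"model": model, "estimator": col, "predictor": "NA",
                             "lmg_raw": np.nan, "lmg_norm": np.nan, "r2_full": np.nan,
                             "is_top": False, "pct_total_variance": np.nan,
                             "note": str(exc)})
                continue
            for pred in res.predictors:
                rows.append({
                    "model": model, "estimator": col, "predictor": pred,
                    "lmg_raw": float(res.lmg_raw[pred]),
                    "lmg_norm": float(res.lmg_norm[pred]),
                    "r2_full": res.r2_full,
                    "is_top": pred == res.top_predictor,
                    "pct_total_variance": (res.pct_total_variance
                                           if pred == res.top_predictor else np.nan),
                    "note": "",
                })
    return pd.DataFrame(rows)
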