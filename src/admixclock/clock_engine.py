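"""Linear DNA-methylation estimators and age-adjusted acceleration measures.

Every estimator supported here is a linear predictor over CpG beta values,
``score = intercept + sum_j coef_j * beta_j``, optionally passed through the
piecewise log/linear age transform used by the Horvath-style calculators.
Age-kind clocks become *acceleration* columns (OLS residual of DNAm age on
chronological age); surrogate-kind estimators become age-residualized levels.
The intrinsic (IEAA) and extrinsic (EEAA) variants additionally involve
blood-cell-composition covariates supplied in the sample metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ClockDefinition, SchemaError, logger


class CoverageError(ValueError):
    """Too many clock CpGs missing from the beta matrix."""


# ---------------------------------------------------------------------------
# Linear predictor and age transform
# ---------------------------------------------------------------------------

def linear_predictor(betas: pd.DataFrame, clock: ClockDefinition,
                     missing_policy: str = "mean",
                     min_coverage: float = 0.5) -> pd.Series:
    """Per-sample clock score ``intercept + sum(coef * beta)``.

    Parameters
    ----------
    betas
        CpG x sample matrix, values in [0, 1] (NaN allowed).
    missing_policy
        How to fill a clock CpG that is absent from the matrix or NaN for a
        sample: ``"mean"`` imputes the cohort mean beta of that CpG (falling
        back to 0.5 when the CpG is absent entirely), ``"half"`` uses 0.5,
        ``"zero"`` uses 0.
    min_coverage
        Minimum fraction of clock CpGs that must be present in the matrix.
    """
    cpgs = clock.coefficients.index
    present = cpgs[cpgs.isin(betas.index)]
    coverage = len(present) / len(cpgs)
    if coverage < min_coverage:
        missing = sorted(set(cpgs) - set(present))
        raise CoverageError(
            f"clock {clock.name!r}: only {coverage:.0%} of CpGs present "
            f"(floor {min_coverage:.0%}); missing e.g. {missing[:5]}")
    fill = {"mean": np.nan, "half": 0.5, "zero": 0.0}
    if missing_policy not in fill:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sub = betas.reindex(cpgs)
    if missing_policy == "mean":
        row_means = sub.mean(axis=1)
        sub = sub.T.fillna(row_means).T.fillna(0.5)
    else:
        sub = sub.fillna(fill[missing_policy])
    score = clock.intercept + sub.mul(clock.coefficients, axis=0).sum(axis=0)
    score.name = clock.name
    return score


def age_transform(age: np.ndarray | float, adult_age: float = 20.0):
    """Forward age transform: log-compressed below ``adult_age``, linear above."""
    age = np.asarray(age, dtype=float)
    out = np.where(age <= adult_age,
                   np.log1p(age) - np.log1p(adult_age),
                   (age - adult_age) / (adult_age + 1.0))
    return out if out.shape else float(out)


def inverse_age_transform(x: np.ndarray | float, adult_age: float = 20.0):
    """Map a transformed clock score back to years (continuous, monotone)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x <= 0,
                   (1.0 + adult_age) * np.exp(x) - 1.0,
                   (1.0 + adult_age) * x + adult_age)
    return out if out.shape else float(out)


def clock_estimate(betas: pd.DataFrame, clock: ClockDefinition, **kw) -> pd.Series:
    """Raw estimate on the clock's output scale (years for age clocks)."""
    score = linear_predictor(betas, clock, **kw)
    if clock.transform == "horvath":
        return pd.Series(inverse_age_transform(score.to_numpy(), clock.adult_age),
                         index=score.index, name=score.name)
    return score


# ---------------------------------------------------------------------------
# Age adjustment (acceleration residuals)
# ---------------------------------------------------------------------------

def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def age_adjust(estimates: pd.Series, ages: pd.Series) -> pd.Series:
    """Acceleration residuals: OLS of the estimate on chronological age.

    Residuals have mean zero; positive values mean "epigenetically older than
    chronological age predicts" relative to the cohort trend.
    """
    est, age = estimates.align(ages, join="inner")
    if len(est) < 3:
        raise ValueError("age_adjust needs at least 3 samples")
    a = age.to_numpy(dtype=float)
    if np.ptp(a) == 0:
        raise ValueError("constant ages: acceleration residual undefined")
    resid = _ols_residuals(est.to_numpy(dtype=float), a[:, None])
    return pd.Series(resid, index=est.index, name=estimates.name)


def ieaa(estimates: pd.Series, ages: pd.Series, cell_fractions: pd.DataFrame) -> pd.Series:
    """Intrinsic acceleration: residual on age plus cell-composition columns.

    One cell column is dropped to break the simplex collinearity (fractions
    sum to one).  Raises on any remaining rank deficiency, naming the columns.
    """
    est = estimates.loc[cell_fractions.index]
    age = ages.loc[cell_fractions.index].to_numpy(dtype=float)
    cells = cell_fractions.iloc[:, :-1]  # drop last simplex column
    varying = (cells.max(axis=0) - cells.min(axis=0)) > 0
    if not varying.all():
        logger.warning("ieaa: dropping zero-variance cell columns %s",
                       list(cells.columns[~varying]))
        cells = cells.loc[:, varying]
    X = np.column_stack([age, cells.to_numpy(dtype=float)])
    design = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design; check collinearity among age and {list(cells.columns)}")
    resid = _ols_residuals(est.to_numpy(dtype=float), X)
    return pd.Series(resid, index=est.index, name=f"{estimates.name}_IEAA")


def eeaa(hannum_estimates: pd.Series, ages: pd.Series,
         aging_cells: pd.DataFrame, weights=None) -> pd.Series:
    """Extrinsic acceleration: age-residual of a weighted blood-composition-

    enriched version of the Hannum-type estimate.  The estimate and the three
    age-associated cell measures are z-scored, combined with ``weights``
    (default equal), rescaled back to the units of the Hannum estimate, and
    then age-adjusted.  Zero-variance components are excluded with a warning.
    """
    if aging_cells.shape[1] != 3:
        raise SchemaError("eeaa expects exactly three aging-cell columns")
    comps = pd.concat([hannum_estimates.rename("hannum"), aging_cells], axis=1)
    if weights is None:
        weights = np.ones(comps.shape[1])
    weights = np.asarray(weights, dtype=float)
    sd = comps.std(axis=0, ddof=1).to_numpy()
    keep = sd > 0
    if not keep.all():
        dropped = list(comps.columns[~keep])
        logger.warning("eeaa: dropping zero-variance components %s", dropped)
    comps_k = comps.loc[:, keep]
    w = weights[keep]
    z = (comps_k - comps_k.mean()) / comps_k.std(ddof=1)
    combo = (z * w).sum(axis=1) / w.sum()
    # back to Hannum units so the residual is interpretable in years
    combo = combo * hannum_estimates.std(ddof=1) + hannum_estimates.mean()
    combo.name = f"{hannum_estimates.name}_EEAA"
    return age_adjust(combo, ages)


def compute_all(betas: pd.DataFrame, clocks: list[ClockDefinition],
                metadata: pd.DataFrame, **kw) -> pd.DataFrame:
    """One adjusted column per clock, in the given clock order.

    Age-kind clocks yield acceleration residuals (years); surrogate-kind
    clocks yield age-residualized levels in their own units.  A failure in
    one clock is logged and skipped; the others are still computed.
    """
    ages = pd.Series(metadata["age"].to_numpy(dtype=float),
                     index=metadata["sample_id"].to_numpy())
    cols: dict[str, pd.Series] = {}
    for clock in clocks:
        try:
            est = clock_estimate(betas, clock, **kw)
            cols[clock.name] = age_adjust(est, ages)
        except (CoverageError, ValueError) as exc:
            logger.warning("clock %s failed: %s", clock.name, exc)
    out = pd.DataFrame(cols)
    out.index.name = "sample_id"
    return out
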