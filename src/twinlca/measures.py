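"""Preprocessing computations for epigenetic aging analyses.

Beta values from array intensities, age acceleration as a regression
residual, SD-based outlier screening, pubertal development scoring,
covariate adjustment, and twin intraclass correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def beta_value(M, U, offset: float = 100.0):
    """Methylation beta value ``M / (M + U + offset)``.

    ``M`` and ``U`` are methylated/unmethylated probe intensities; the
    offset stabilises the ratio at low total intensity.  Strictly increasing
    in M and strictly decreasing in U; lies in [0, 1) for offset > 0.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    return M / (M + U + offset)


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y on X (intercept included by caller); NaN-safe listwise."""
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if ok.sum() <= X.shape[1]:
        raise ValueError("too few complete observations for the regression")
    rank = np.linalg.matrix_rank(X[ok])
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid = np.full_like(y, np.nan, dtype=float)
    resid[ok] = y[ok] - X[ok] @ beta
    return resid


def age_acceleration(epigenetic_age, chronological_age) -> np.ndarray:
    """Age acceleration: OLS residual of epigenetic age on chronological age.

    Positive values mean the estimated epigenetic age exceeds the value
    expected at the individual's chronological age.  Residuals sum to zero
    and are uncorrelated with chronological age over complete cases.
    """
    ea = np.asarray(epigenetic_age, dtype=float)
    ca = np.asarray(chronological_age, dtype=float)
    if ea.shape != ca.shape or ea.ndim != 1 or ea.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    ok = np.isfinite(ea) & np.isfinite(ca)
    if np.nanstd(ca[ok]) == 0:
        raise ValueError("chronological age is constant: singular design")
    X = np.column_stack([np.ones_like(ca), ca])
    return _ols_residuals(ea, X)


def screen_outliers(values, k: float = 5.0) -> tuple[np.ndarray, int]:
    """Recode values more than ``k`` SDs from the mean as missing.

    Single pass: the mean and SD are computed once, over the non-missing
    input values, and every value with ``|v - mean| > k * SD`` is set to NaN.
    Returns the recoded vector and the number of values recoded.  A zero SD
    (all values identical) yields no recodes.
    """
    v = np.asarray(values, dtype=float).copy()
    obs = np.isfinite(v)
    if not obs.any():
        raise ValueError("all values missing")
    if obs.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = v[obs].mean()
    sd = v[obs].std(ddof=1)
    if sd == 0:
        return v, 0
    out = obs & (np.abs(v - mean) > k * sd)
    v[out] = np.nan
    return v, int(out.sum())


def pds_score(items) -> float:
    """Pubertal development score: mean of the five maturation items.

    Items are coded 1 (not begun), 2 (barely started), 3 (definitely
    underway); the menarche item is dichotomous (1 or 3).  Higher scores
    indicate more advanced pubertal development; the mean lies in [1, 3].
    """
    a = np.asarray(items, dtype=float)
    if a.shape != (5,):
        raise ValueError("exactly five items required")
    if not np.all(np.isin(a, (1.0, 2.0, 3.0))):
        raise ValueError("item codes must be in {1, 2, 3}")
    return float(a.mean())


def adjust_outcome(outcome, covariates) -> np.ndarray:
    """Residualise an outcome on covariates (intercept added automatically).

    Rows with any missing covariate or outcome value are dropped from the
    fit and returned as NaN.  Residuals have mean zero and are orthogonal to
    every covariate column over the complete cases.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("outcome and covariates must have equal length")
    design = np.column_stack([np.ones(len(y)), X])
    return _ols_residuals(y, design)


@dataclass
class ICCResult:
    """Intraclass correlation for one zygosity group."""

    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int
    method: str

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.icc, self.ci_low, self.ci_high)


def _double_entry_icc(pairs: np.ndarray) -> float:
    """Pairwise (double-entry) Pearson correlation."""
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return float(np.corrcoef(x, y)[0, 1])


def _anova_icc(pairs: np.ndarray) -> float:
    """One-way random-effects ICC: (MSB - MSW) / (MSB + MSW) for pairs."""
    n = pairs.shape[0]
    pair_means = pairs.mean(axis=1)
    grand = pairs.mean()
    msb = 2 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((pairs - pair_means[:, None]) ** 2) / n
    return float((msb - msw) / (msb + msw))


def twin_icc(
    pairs: np.ndarray,
    conf_level: float = 0.95,
    method: str = "double_entry",
) -> ICCResult:
    """Twin intraclass correlation on complete pairs with a Fisher-z CI.

    ``pairs`` is an (n, 2) array of one outcome measured on both members of
    each pair; rows with a missing member are dropped.  The default point
    estimate is the pairwise (double-entry) Pearson correlation; the one-way
    random-effects ANOVA estimator is available as ``method="anova"``.  The
    CI applies the Fisher z transform with the number of complete pairs as
    the effective sample size.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    complete = pairs[np.all(np.isfinite(pairs), axis=1)]
    n = complete.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "double_entry":
        icc = _double_entry_icc(complete)
    elif method == "anova":
        icc = _anova_icc(complete)
    else:
        raise ValueError(f"unknown ICC method {method!r}")
    icc = float(np.clip(icc, -1.0, 1.0))
    if n > 3 and abs(icc) < 1:
        z = np.arctanh(icc)
        se = 1.0 / np.sqrt(n - 3)
        crit = stats.norm.ppf(0.5 + conf_level / 2)
        lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    else:
        lo = hi = icc
    return ICCResult(icc=icc, ci_low=float(lo), ci_high=float(hi), n_pairs=n, method=method)


def icc_by_zygosity(
    cohort: pd.DataFrame, outcome: str, method: str = "double_entry"
) -> dict[str, ICCResult]:
    """ICC per pooled zygosity (MZ vs DZ) from a per-individual cohort table."""
    out: dict[str, ICCResult] = {}
    zyg = cohort["zygosity"].astype(str).str.upper()
    pooled = np.where(zyg.str.startswith("MZ"), "MZ", "DZ")
    for label in ("MZ", "DZ"):
        sub = cohort.loc[pooled == label, ["family_id", "member_index", outcome]]
        wide = sub.pivot(index="family_id", columns="member_index", values=outcome)
        out[label] = twin_icc(wide.to_numpy(), method=method)
    return out
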