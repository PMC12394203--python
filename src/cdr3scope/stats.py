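"""Statistical layer: correlation, group tests, multiplicity control, star codes.

All correlation screens in the pipeline go through :func:`correlation_report`,
which computes Pearson r with its two-sided t-approximation p-value per
feature, applies Benjamini-Hochberg step-up FDR control across the family,
and attaches the conventional significance stars.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def pearson_with_test(x, y) -> tuple[float, float, int]:
    """Pearson r and two-sided p (t approximation); pairs with missing entries dropped.

    Returns (nan, nan, n) when either variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"pearson_with_test requires n >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan, n)
    r, p = sps.pearsonr(x, y)
    return (float(r), float(p), n)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U (a vs b).

    Exact enumeration is used for small samples without ties (min n <= 8),
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return (float(res.statistic), float(res.pvalue))


def f_variance_ratio(std1: float, n1: int, std2: float, n2: int) -> tuple[float, float]:
    """Variance-ratio F statistic std1^2/std2^2 with two-sided p.

    The numerator is taken as given (no automatic reordering), so F < 1 is a
    legitimate outcome; p = 2 * min(lower tail, upper tail) on F(n1-1, n2-1).
    """
    if std1 <= 0 or std2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample must have n >= 2")
    F = (std1 / std2) ** 2
    dist = sps.f(n1 - 1, n2 - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return (float(F), float(min(p, 1.0)))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


#: Significance star bins.  The conventional printed map leaves the exact
#: boundaries at 0.01 and 0.001 ambiguous; this package uses half-open bins
#: (0.01, 0.05] -> *, [0.001, 0.01] -> **, [0.0001, 0.001) -> ***,
#: <= 0.0001 -> ****, closing the boundary at exactly 0.01 into **.
def stars(p: float) -> str:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def binned_mean_regression(x, y) -> dict:
    """OLS line fitted to per-length mean values (for presentation alongside
    all-points Pearson correlations).

    Groups y by integer x, fits ordinary least squares to the (x, mean-y)
    pairs, and returns per-bin n / mean / standard error for error bars.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    groups = df.groupby("x")["y"]
    bins = pd.DataFrame({
        "x": groups.mean().index.to_numpy(dtype=float),
        "n": groups.size().to_numpy(),
        "mean": groups.mean().to_numpy(),
        "se": (groups.std(ddof=1) / np.sqrt(groups.size())).to_numpy(),
    })
    if len(bins) < 3:
        raise ValueError("binned_mean_regression requires >= 3 distinct x values")
    slope, intercept = np.polyfit(bins["x"], bins["mean"], 1)
    return {"slope": float(slope), "intercept": float(intercept), "bins": bins}


def correlation_report(
    df: pd.DataFrame,
    x_col: str,
    feature_cols: list[str],
    group: str = "",
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Pearson-vs-``x_col`` screen over ``feature_cols`` with BH-FDR and stars.

    Features with zero variance (r undefined) are reported with NaN r/p and
    excluded from the BH family.
    """
    rows = []
    for col in feature_cols:
        try:
            r, p, n = pearson_with_test(df[x_col], df[col])
        except ValueError:
            r, p, n = math.nan, math.nan, int(df[[x_col, col]].dropna().shape[0])
        rows.append({"feature": col, "group": group, "n": n, "r": r, "p_raw": p})
    report = pd.DataFrame(rows, columns=["feature", "group", "n", "r", "p_raw"])
    report["p_adj"] = math.nan
    tested = report["p_raw"].notna()
    if tested.any():
        report.loc[tested, "p_adj"] = bh_fdr(report.loc[tested, "p_raw"].to_numpy())
    report["stars"] = [stars(p) if np.isfinite(p) else "na" for p in report["p_adj"]]
    report["significant"] = report["p_adj"] < fdr_level
    return report
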