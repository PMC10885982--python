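"""Agreement and group-comparison statistics for device validation.

Covers the statistics used to validate a new force-measurement device
against a stationary dynamometer and to characterize a post-stroke
cohort: ICC(2,1) (two-way random effects, absolute agreement, single
measurement) with F-based confidence intervals, Bland-Altman limits of
agreement, one-way ANOVA with eta-squared effect sizes (noncentral-F
confidence intervals) and Sidak-corrected pairwise comparisons, Pearson
correlation, and the distance-induced change in six-minute-walk-test
speed (%delta-6MWT).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sst

__all__ = [
    "AgreementResult",
    "GroupComparison",
    "icc_2_1",
    "bland_altman",
    "one_way_anova_eta",
    "sidak_pairwise",
    "pearson_r",
    "pct_delta_6mwt",
]


@dataclass(frozen=True)
class AgreementResult:
    """Inter-device agreement: ICC and/or Bland-Altman bias with limits."""

    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    bias: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None
    diff_sd: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA outcome with effect size and pairwise comparisons."""

    f_statistic: float
    p_value: float
    eta_squared: float
    eta_squared_ci: tuple[float, float]
    pairwise: dict[tuple, float]
    group_means: dict | None = None


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    ``ratings`` is an n-subjects x k-raters matrix with no missing cells.
    The coefficient is computed from the two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC, MSE are the mean squares for rows (subjects),
    columns (raters), and error.  Absolute agreement penalizes a
    systematic offset between raters, unlike the consistency form.
    The CI is the F-based interval for this ICC form.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n, k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("degenerate ratings: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI (two-way random, absolute agreement, single measure) with
    # a Satterthwaite df for the denominator.  A zero error mean square
    # (exact agreement up to a constant offset) degenerates the F ratios;
    # the interval collapses onto the point estimate.
    if mse <= 1e-12 * max(msr, msc, 1e-300):
        return AgreementResult(icc=float(icc), icc_ci=(float(icc), float(icc)))
    fj = msc / mse
    df_err = (n - 1) * (k - 1)
    b = n * (1 + (k - 1) * icc) - k * icc
    a = k * icc * fj + b
    v = (df_err * a**2) / ((n - 1) * k**2 * icc**2 * fj**2 + b**2)
    f_u = sst.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sst.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return AgreementResult(icc=float(icc), icc_ci=(float(lower), float(upper)))


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement: bias = mean(b - a), LoA = bias +/- 1.96 SD.

    The SD of the paired differences uses the n-1 denominator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("at least 2 pairs required")
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, diff_sd=sd
    )


def _eta_squared_ci(
    f_obs: float, df1: int, df2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """CI for eta-squared by inverting the noncentral-F distribution.

    Bounds on the noncentrality parameter lambda are found such that the
    observed F sits at the alpha/2 tails, then mapped through
    eta^2 = lambda / (lambda + N) with N = df1 + df2 + 1.
    """
    n_total = df1 + df2 + 1

    def eta(lam: float) -> float:
        return lam / (lam + n_total)

    def _cdf(lam: float) -> float:
        # cdf degrades to NaN for extreme noncentrality; treat as 0
        c = sst.ncf.cdf(f_obs, df1, df2, lam)
        return 0.0 if np.isnan(c) else float(c)

    def upper_eq(lam: float) -> float:
        return _cdf(lam) - alpha / 2

    def lower_eq(lam: float) -> float:
        # survival function via the cdf (ncf.sf is unreliable at lam = 0)
        return (1.0 - _cdf(lam)) - alpha / 2

    def _solve(eq) -> float:
        # eq is monotone decreasing in lambda; plain bisection is robust
        # to the flat/NaN tail regions where brentq can stall
        lo, hi = 0.0, max(f_obs * n_total, 10.0)
        for _ in range(60):
            if eq(hi) < 0:
                break
            hi *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if eq(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-10 * (1.0 + hi):
                break
        return 0.5 * (lo + hi)

    # lower bound: largest lambda placing f_obs in the upper alpha/2 tail;
    # 0 when even the central F makes f_obs unremarkable
    lo = 0.0 if lower_eq(0.0) >= 0 else eta(_solve(lambda lam: -lower_eq(lam)))
    hi = 0.0 if upper_eq(0.0) <= 0 else eta(_solve(upper_eq))
    return (min(lo, hi), max(lo, hi))


def one_way_anova_eta(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with eta-squared (SS_between / SS_total) and 95% CI."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_total = float(np.sum((all_x - grand) ** 2))
    df1 = len(arrays) - 1
    df2 = all_x.size - len(arrays)
    if ss_total == 0:
        return GroupComparison(0.0, 1.0, 0.0, (0.0, 0.0), sidak_pairwise(arrays))
    eta2 = float(ss_between / ss_total)
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        # perfect separation: infinite F
        return GroupComparison(np.inf, 0.0, 1.0, (0.0, 1.0), sidak_pairwise(arrays))
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(sst.f.sf(f_stat, df1, df2))
    ci = _eta_squared_ci(f_stat, df1, df2)
    return GroupComparison(float(f_stat), p, eta2, ci, sidak_pairwise(arrays))


def sidak_pairwise(
    groups: Sequence[Sequence[float]], labels: Sequence | None = None
) -> dict[tuple, float]:
    """Sidak-adjusted pairwise two-sample t tests (pooled variance).

    Adjusted p = 1 - (1 - p_raw)^m over the m = C(g, 2) pairs.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = list(range(len(arrays)))
    pairs = list(combinations(range(len(arrays)), 2))
    m = len(pairs)
    out: dict[tuple, float] = {}
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if a.size < 2 or b.size < 2:
            raise ValueError("degenerate group: fewer than 2 values")
        if a.std() == 0 and b.std() == 0:
            # zero pooled variance: identical means agree, different ones differ
            p_raw = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p_raw = float(sst.ttest_ind(a, b, equal_var=True).pvalue)
        out[(labels[i], labels[j])] = sidak_adjust(p_raw, m)
    return out


def sidak_adjust(p_raw: float, m: int) -> float:
    """Sidak family-wise adjustment of a single raw p-value over m tests."""
    if not (0 <= p_raw <= 1):
        raise ValueError("p_raw must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p_raw) ** m)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    res = sst.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pct_delta_6mwt(minute_distances: Sequence[float]) -> float:
    """Distance-induced change in 6MWT speed, percent.

    100 * (d6 - d1) / d1 over the six per-minute distances; positive
    values mean the participant sped up over the test.
    """
    d = np.asarray(minute_distances, dtype=float)
    if d.size != 6:
        raise ValueError("exactly 6 minute distances required")
    if np.any(d < 0):
        raise ValueError("minute distances must be nonnegative")
    if d[0] == 0:
        raise ValueError("first-minute distance must be positive")
    return float(100.0 * (d[5] - d[0]) / d[0])
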