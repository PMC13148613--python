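"""Distribution summaries and rank-based sample comparisons.

Per-region parameter distributions (D-period, peak widths, lattice
spacings, intensity ratios over thousands of scan points) are summarized
box-plot style and compared across samples with the two-sided Wilcoxon
rank-sum (Mann-Whitney U) test.  The populations compared are unpaired
pixel sets of unequal size, for which the signed-rank test is undefined;
a paired signed-rank variant is available for equal-length paired inputs.
Significance stars follow the conventional mapping: p <= 0.05 '*',
p <= 0.01 '**', p <= 0.001 '***', otherwise 'ns'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class DistributionSummary:
    """Box-plot summary: quartiles, 1.5 IQR whiskers, outlier count."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n_outliers: int


@dataclass
class ComparisonResult:
    statistic: float     # Mann-Whitney U (of the first sample)
    p_value: float
    stars: str
    n_a: int
    n_b: int
    test: str = "rank-sum"


def stars_for_p(p: float) -> str:
    for level, s in STAR_LEVELS:
        if p <= level:
            return s
    return "ns"


def summarize(values) -> DistributionSummary:
    """Box-plot summary of a sample (NaN entries dropped).

    Quartiles use linear interpolation; whiskers reach the most extreme
    data point within 1.5 IQR of the respective quartile.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return DistributionSummary(
        n=int(v.size), median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        n_outliers=int(v.size - inside.size),
    )


def compare_distributions(a, b, exact_max_n: int = 8) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    Exact enumeration of the U distribution when both samples have at most
    ``exact_max_n`` observations and no ties span the samples; otherwise
    the tie-corrected normal approximation.  Fully tied data yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return ComparisonResult(statistic=a.size * b.size / 2.0, p_value=1.0,
                                stars="ns", n_a=a.size, n_b=b.size)
    has_ties = np.unique(combined).size < combined.size
    method = ("exact" if (a.size <= exact_max_n and b.size <= exact_max_n
                          and not has_ties) else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(statistic=float(res.statistic), p_value=p,
                            stars=stars_for_p(p), n_a=a.size, n_b=b.size)


def compare_paired(a, b) -> ComparisonResult:
    """Wilcoxon signed-rank test for equal-length paired samples.

    Provided for genuinely paired designs; unpaired pixel populations of
    different sizes should use :func:`compare_distributions` (logged note).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signed-rank test requires equal-length paired samples")
    log.info("signed-rank test applied; use compare_distributions for "
             "unpaired populations")
    if np.all(a == b):
        return ComparisonResult(statistic=0.0, p_value=1.0, stars="ns",
                                n_a=a.size, n_b=b.size, test="signed-rank")
    res = sps.wilcoxon(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return ComparisonResult(statistic=float(res.statistic), p_value=p,
                            stars=stars_for_p(p), n_a=a.size, n_b=b.size,
                            test="signed-rank")


def percent_change(median_x: float, median_ref: float) -> float:
    """100 * (median_x - median_ref) / median_ref."""
    if median_ref == 0:
        raise ValueError("reference median must be nonzero")
    return 100.0 * (median_x - median_ref) / median_ref
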