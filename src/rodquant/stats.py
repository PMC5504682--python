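"""Downstream group statistics for the morphometry and halo assays.

Covers the four quantitative summaries used on top of the image pipelines:
the two-sided Wilcoxon rank-sum comparison of cell-length distributions, the
linear sensitivity-vs-dose validation of the squared-radius statistic, the
with/without protection ratio, and Tukey boxplot descriptors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress, norm, rankdata

__all__ = [
    "GroupComparison",
    "DoseResponseFit",
    "BoxplotSummary",
    "rank_sum_test",
    "dose_linearity",
    "protection_ratio",
    "boxplot_summary",
]

EXACT_MAX_N = 12  # full enumeration is used up to this combined sample size


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample rank-sum comparison.

    ``percent_change`` is 100 * (mean2 - mean1) / mean1, the convention used
    when reporting an average cell-length increase; medians are carried along
    because length distributions are skewed and typically plotted by median.
    """

    n1: int
    n2: int
    median1: float
    median2: float
    mean1: float
    mean2: float
    u_statistic: float  # Mann-Whitney U of the first sample
    rank_sum: float  # Wilcoxon W: rank sum of the first sample
    p_two_sided: float
    percent_change: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class DoseResponseFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey box descriptors: quartiles, whiskers at the most extreme data
    within 1.5 IQR of the box, points beyond flagged as outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _exact_two_sided_p(u1: float, n1: int, n2: int) -> float:
    """Doubled smaller tail of the exact null distribution of U, capped at 1.

    Enumerates all C(n1+n2, n1) assignments of the (tie-free) ranks 1..n1+n2
    to the first sample.
    """
    n = n1 + n2
    offset = n1 * (n1 + 1) / 2.0
    n_le = n_ge = total = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        u = sum(combo) - offset
        total += 1
        if u <= u1 + 1e-9:
            n_le += 1
        if u >= u1 - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum_test(
    x,
    y,
    method: str = "auto",
    continuity: bool = True,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    The exact null distribution is enumerated when the combined sample size
    is at most 12 and there are no ties ("auto"); otherwise the normal
    approximation with tie correction and (by default) continuity correction
    is used.  Ties receive mid-ranks.  The two-sided exact p is the doubled
    smaller tail probability, capped at 1.

    Parameters
    ----------
    method : {"auto", "exact", "normal"}
        "exact" forces enumeration (rejected if ties are present or the
        combined size exceeds 12); "normal" forces the approximation.
    continuity : bool
        Apply the 0.5 continuity correction in the normal approximation.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(xa), len(ya)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")

    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)  # mid-ranks for ties
    w1 = float(ranks[:n1].sum())
    u1 = w1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    use_exact = method == "exact" or (
        method == "auto" and n1 + n2 <= EXACT_MAX_N and not has_ties
    )
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        if n1 + n2 > EXACT_MAX_N:
            raise ValueError(f"exact method limited to n1+n2 <= {EXACT_MAX_N}")

    if use_exact:
        p = _exact_two_sided_p(u1, n1, n2)
        used = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all values identical
            p = 1.0
        else:
            cc = 0.5 if continuity else 0.0
            z = (abs(u1 - mu) - cc) / math.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(z)))
        used = "normal"

    mean1, mean2 = float(xa.mean()), float(ya.mean())
    return GroupComparison(
        n1=n1,
        n2=n2,
        median1=float(np.median(xa)),
        median2=float(np.median(ya)),
        mean1=mean1,
        mean2=mean2,
        u_statistic=u1,
        rank_sum=w1,
        p_two_sided=p,
        percent_change=100.0 * (mean2 - mean1) / mean1,
        method=used,
    )


def dose_linearity(amounts, sensitivities) -> DoseResponseFit:
    """Ordinary least-squares fit of sensitivity (squared halo radius) on
    antibiotic amount; a high R² validates the sensitivity statistic."""
    a = np.asarray(amounts, dtype=float).ravel()
    s = np.asarray(sensitivities, dtype=float).ravel()
    if len(a) != len(s):
        raise ValueError("amounts and sensitivities must have equal length")
    if len(a) < 2 or np.unique(a).size < 2:
        raise ValueError("need at least 2 distinct amounts")
    fit = linregress(a, s)
    return DoseResponseFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(a),
    )


def protection_ratio(s_with: float, s_without: float) -> float:
    """Sensitivity with / without a protective supplement.

    0 means total protection, 0.5 half protection, 1 no effect, 2 a twofold
    increase in sensitivity.
    """
    if s_without <= 0:
        raise ValueError("reference sensitivity must be > 0 (ratio undefined)")
    return s_with / s_without


def boxplot_summary(sample) -> BoxplotSummary:
    """Median, quartiles (linear-interpolation convention), Tukey whiskers
    and outliers of one sample."""
    a = np.asarray(sample, dtype=float).ravel()
    if len(a) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(a, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = a[(a >= lo_fence) & (a <= hi_fence)]
    outliers = a[(a < lo_fence) | (a > hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )
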