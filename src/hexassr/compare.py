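"""Marker-class comparisons: CVs, t-tests, correlations, normality checks.

EST-derived and genomic SSR panels are compared statistic by statistic:
coefficients of variation across loci, two-sample t-tests on per-locus
index values, Pearson correlations between indices, and a
Kolmogorov-Smirnov check of distributional normality (e.g. for pairwise
distance distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = ["CVDenominator", "ComparisonReport", "cv", "two_sample_t", "pearson", "ks_normality"]


class CVDenominator(str, Enum):
    """Population (N) or sample (N-1) standard deviation in the CV."""

    N = "n"
    N_MINUS_1 = "n_minus_1"


@dataclass
class ComparisonReport:
    """Outcome of a two-group comparison of one statistic."""

    statistic_name: str
    mean_x: float
    mean_y: float
    cv_x: float
    cv_y: float
    n_x: int
    n_y: int
    test_name: str
    test_statistic: float
    df: float
    p: float


def cv(values: Sequence[float], denominator: CVDenominator | str = CVDenominator.N) -> float:
    """Coefficient of variation as a percentage, 100 * sd / mean.

    Both sd conventions are in circulation in diversity reports, so the
    denominator (N or N-1) is explicit.
    """
    denominator = CVDenominator(denominator)
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    ddof = 0 if denominator is CVDenominator.N else 1
    return 100.0 * arr.std(ddof=ddof) / mean


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    statistic_name: str = "",
    equal_var: bool = False,
) -> ComparisonReport:
    """Two-sample t-test (Welch by default) comparing a per-locus statistic
    between marker classes."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("t-test needs at least 2 values per group")
    res = _sstats.ttest_ind(xa, ya, equal_var=equal_var)
    if equal_var:
        df = xa.size + ya.size - 2.0
        name = "Student t"
    else:
        vx, vy = xa.var(ddof=1) / xa.size, ya.var(ddof=1) / ya.size
        df = (vx + vy) ** 2 / (vx**2 / (xa.size - 1) + vy**2 / (ya.size - 1))
        name = "Welch t"
    return ComparisonReport(
        statistic_name=statistic_name,
        mean_x=float(xa.mean()),
        mean_y=float(ya.mean()),
        cv_x=cv(xa, CVDenominator.N_MINUS_1),
        cv_y=cv(ya, CVDenominator.N_MINUS_1),
        n_x=int(xa.size),
        n_y=int(ya.size),
        test_name=name,
        test_statistic=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and its two-sided p-value."""
    res = _sstats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(res.statistic), float(res.pvalue)


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and sample sd.  Estimating
    the parameters from the same data makes the test conservative
    (Lilliefors effect): the printed p overstates normality.  Retained
    because it is the convention in the genotyping literature this package
    mirrors; use a Lilliefors table for calibrated inference.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("KS normality test needs at least 3 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("KS normality test undefined for constant data")
    res = _sstats.kstest(arr, "norm", args=(arr.mean(), sd))
    return float(res.statistic), float(res.pvalue)
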