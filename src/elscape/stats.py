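"""Gini polarization indices, group comparisons, and behavior correlations.

The Gini coefficient of a nonnegative vector x is the mean-absolute-
difference form

    G = sum_ij |x_i - x_j| / (2 n^2 mu),

a scale-free index in [0, (n-1)/n]: 0 for a perfectly uniform vector, close
to 1 when mass concentrates on few entries.  Applied to per-attractor
dwelling times and pairwise transition counts it quantifies how polarized
the landscape dynamics are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    t: float
    df: float
    p_raw: float
    p_bonferroni: float
    eta_sq: float
    n_a: int
    n_b: int


@dataclass
class BehaviorCorrelation:
    r: float
    n: int
    p: float
    defined: bool = True


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a nonnegative vector (0 for degenerate inputs).

    A length-1 or all-zero vector carries no inequality to measure and
    returns 0; use :func:`gini_defined` to distinguish that case.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("values must be a non-empty 1-D vector")
    if np.any(x < 0):
        raise ValueError("values must be nonnegative")
    if not gini_defined(x):
        return 0.0
    n = x.size
    # scale invariance lets us normalize by the maximum first, which keeps
    # the ratio finite even for subnormal inputs
    xs = np.sort(x / x.max())
    # sorted-rank identity for sum_ij |x_i - x_j|
    ranks = np.arange(1, n + 1)
    total_abs_diff = 2.0 * np.sum((2 * ranks - n - 1) * xs)
    return float(total_abs_diff / (2.0 * n * n * xs.mean()))


def gini_defined(values: np.ndarray) -> bool:
    """Whether the Gini index is informative: length ≥ 2 and positive mean."""
    x = np.asarray(values, dtype=float)
    return x.size >= 2 and x.sum() > 0


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    n_comparisons: int = 1,
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test with Bonferroni correction and eta-squared effect size.

    Pooled-variance by default (Welch via ``welch=True``);
    eta² = t² / (t² + df).  Two groups with zero variance and equal means
    give t = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    df = float(res.df)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant with equal means
        t, p = 0.0, 1.0
        if np.isnan(df):
            df = a.size + b.size - 2
    eta_sq = t * t / (t * t + df) if df > 0 else 0.0
    return GroupComparison(
        t=t,
        df=df,
        p_raw=p,
        p_bonferroni=min(1.0, p * n_comparisons),
        eta_sq=eta_sq,
        n_a=a.size,
        n_b=b.size,
    )


def correlate_with_behavior(indices: np.ndarray, scores: np.ndarray) -> BehaviorCorrelation:
    """Pearson correlation between per-subject indices and behavioral scores."""
    x = np.asarray(indices, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("indices and scores must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return BehaviorCorrelation(r=float("nan"), n=x.size, p=float("nan"), defined=False)
    r, p = sps.pearsonr(x, y)
    return BehaviorCorrelation(r=float(r), n=x.size, p=float(p), defined=True)
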