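"""Group-comparison statistics for morphometry and rescue experiments."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    group_summaries: tuple[tuple[float, float, int], ...]  # (mean, sd, n)
    test_variant: str  # "student" | "welch"


def unpaired_t_test(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student",
    two_sided: bool = True,
) -> TestResult:
    """Unpaired t test, pooled-variance (Student) by default, Welch optional.

    Degenerate inputs get defined outputs rather than exceptions: groups
    smaller than 2 or zero pooled variance with equal means give t=0, p=1;
    zero variance with unequal means gives a p=0 sentinel with a warning.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    n1, n2 = len(xa), len(ya)
    m1 = float(xa.mean()) if n1 else math.nan
    m2 = float(ya.mean()) if n2 else math.nan
    s1 = float(xa.std(ddof=1)) if n1 > 1 else 0.0
    s2 = float(ya.std(ddof=1)) if n2 > 1 else 0.0
    summaries = ((m1, s1, n1), (m2, s2, n2))
    if n1 < 2 or n2 < 2:
        warnings.warn("group smaller than 2; returning t=0, p=1")
        return TestResult(0.0, 1.0, 1.0, summaries, variant)
    if variant == "student":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (
                v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
            )
        else:
            df = float(n1 + n2 - 2)
    if se == 0.0:
        if m1 == m2:
            return TestResult(0.0, 1.0, df, summaries, variant)
        warnings.warn("zero variance with unequal means; p=0 sentinel")
        t = math.inf if m1 > m2 else -math.inf
        return TestResult(t, 0.0, df, summaries, variant)
    t = (m1 - m2) / se
    if two_sided:
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        p = sps.t.sf(t, df)
    return TestResult(float(t), float(min(p, 1.0)), df, summaries, variant)


def ratio_of_means(
    numerator_mean: float, denominator_mean: float, decimals: int = 3
) -> float:
    """Rounded quotient of two group means (e.g. lens area / eye area)."""
    if denominator_mean == 0:
        raise ValueError("zero denominator")
    return round(numerator_mean / denominator_mean, decimals)


def mean_of_ratios(
    numerators: Sequence[float], denominators: Sequence[float], decimals: int = 3
) -> float:
    """Mean of per-subject ratios -- the alternative summary convention.

    Reported alongside :func:`ratio_of_means` because published per-group
    ratios are not always arithmetically consistent with the ratio of the
    printed group means; the two conventions differ under between-subject
    variability.
    """
    num = np.asarray(numerators, float)
    den = np.asarray(denominators, float)
    if num.shape != den.shape or num.size == 0:
        raise ValueError("need equal-length, non-empty vectors")
    if np.any(den == 0):
        raise ValueError("zero denominator")
    return round(float(np.mean(num / den)), decimals)


def rescue_fraction(outcomes: Sequence[str]) -> float:
    """Percent of embryos labelled "normal", to one decimal."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes")
    bad = set(outcomes) - {"normal", "abnormal"}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    n_normal = sum(1 for o in outcomes if o == "normal")
    return round(100.0 * n_normal / len(outcomes), 1)
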