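"""Cohort statistics: descriptives, one-way ANOVA with Fisher's LSD,
Student's t-tests and intraclass correlation coefficients.

These mirror the analysis toolkit of a typical clinical morphometry study:
mean ± SD tables, one-way ANOVA with least-significant-difference pairwise
comparisons, two-sided t-tests, and variance-component ICCs for intra- and
inter-observer reliability.  All tests are two-sided; no multiplicity
correction is applied beyond LSD itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "DescriptiveStats",
    "AnovaResult",
    "TTestResult",
    "IccResult",
    "describe",
    "one_way_anova_lsd",
    "t_test",
    "icc",
]


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    sd: Optional[float]  # n-1 denominator; None when n < 2


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Mean and sample (n−1) standard deviation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("describe requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("describe requires finite values")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return DescriptiveStats(n=int(arr.size), mean=float(arr.mean()), sd=sd)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    pairwise: Dict[Tuple[int, int], float]  # (i, j) group indices -> LSD p
    degenerate: bool = False  # zero within-variance with unequal means


def one_way_anova_lsd(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with Fisher's LSD post hoc.

    LSD pairwise p-values use t = (m_i − m_j) / sqrt(MSw (1/n_i + 1/n_j))
    on the within-groups degrees of freedom; for two groups this is
    algebraically the pooled-variance two-sample t-test.

    Zero within-group variance with unequal means is reported with the
    ``p = 0`` convention and flagged ``degenerate``.
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("ANOVA requires at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValidationError("every ANOVA group needs n >= 2")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    n_total = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_between = len(gs) - 1
    df_within = n_total - len(gs)
    if df_within < 1:
        raise ValidationError("insufficient observations: within df < 1")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    degenerate = ms_within == 0.0
    if degenerate:
        equal = np.allclose(means, means[0])
        F = 0.0 if equal else float("inf")
        p = 1.0 if equal else 0.0
    else:
        F = ms_between / ms_within
        p = float(sps.f.sf(F, df_between, df_within))

    pairwise: Dict[Tuple[int, int], float] = {}
    for i, j in combinations(range(len(gs)), 2):
        if degenerate:
            pairwise[(i, j)] = 1.0 if means[i] == means[j] else 0.0
            continue
        se = np.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]))
        t = (means[i] - means[j]) / se
        pairwise[(i, j)] = float(2.0 * sps.t.sf(abs(t), df_within))

    return AnovaResult(
        F=F,
        p=p,
        df_between=df_between,
        df_within=df_within,
        ms_within=ms_within,
        pairwise=pairwise,
        degenerate=degenerate and not np.allclose(means, means[0]),
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    paired: bool
    degenerate: bool = False  # zero variance: t/p are not meaningful


def t_test(a: Sequence[float], b: Sequence[float], paired: bool = False) -> TTestResult:
    """Student's t-test, two-sided; pooled variance when unpaired."""
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if paired:
        if x.size != y.size:
            raise ValidationError(
                f"paired t-test needs equal lengths, got {x.size} and {y.size}"
            )
        if x.size < 2:
            raise ValidationError("paired t-test needs n >= 2")
        diff = x - y
        df = x.size - 1
        if diff.std(ddof=1) == 0.0:
            return TTestResult(
                t=0.0, p=1.0 if diff.mean() == 0 else 0.0, df=df,
                paired=True, degenerate=True,
            )
        res = sps.ttest_rel(x, y)
        return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df, paired=True)
    if x.size < 2 or y.size < 2:
        raise ValidationError("unpaired t-test needs n >= 2 per group")
    df = x.size + y.size - 2
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        same = x.mean() == y.mean()
        return TTestResult(t=0.0, p=1.0 if same else 0.0, df=df, paired=False, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=df, paired=False)


ICC_MODELS = ("oneway_random", "twoway_random_absolute", "twoway_mixed_consistency")


@dataclass(frozen=True)
class IccResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def icc(ratings, model: str = "twoway_random_absolute") -> IccResult:
    """Single-measure intraclass correlation from the two-way mean squares.

    ``ratings`` is a subjects × raters matrix with no missing cells.
    Models follow the Shrout–Fleiss taxonomy:

    * ``oneway_random`` — ICC(1,1): raters nested in subjects;
    * ``twoway_random_absolute`` — ICC(2,1): absolute agreement, rater a
      random effect (default; the standard choice for inter-observer
      reliability of continuous measurements);
    * ``twoway_mixed_consistency`` — ICC(3,1): consistency, raters fixed.
    """
    if model not in ICC_MODELS:
        raise ValidationError(f"unknown ICC model {model!r}; expected one of {ICC_MODELS}")
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValidationError("ICC needs a 2D matrix with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(mat)):
        raise ValidationError("ICC matrix has missing or non-finite cells")
    n, k = mat.shape

    grand = mat.mean()
    subj_means = mat.mean(axis=1)
    rater_means = mat.mean(axis=0)
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_rater = n * float(((rater_means - grand) ** 2).sum())
    ss_total = float(((mat - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_rater
    ss_within = ss_total - ss_subj

    msb = ss_subj / (n - 1)  # between subjects
    msw = ss_within / (n * (k - 1))  # within subjects (one-way)
    msj = ss_rater / (k - 1)  # between raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    if model == "oneway_random":
        denom = msb + (k - 1) * msw
        value = (msb - msw) / denom if denom != 0 else 1.0
    elif model == "twoway_random_absolute":
        denom = msb + (k - 1) * mse + k * (msj - mse) / n
        value = (msb - mse) / denom if denom != 0 else 1.0
    else:  # twoway_mixed_consistency
        denom = msb + (k - 1) * mse
        value = (msb - mse) / denom if denom != 0 else 1.0
    return IccResult(icc=float(value), model=model, n_subjects=n, n_raters=k)
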