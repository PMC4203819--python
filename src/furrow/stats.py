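"""Group statistics: unpaired t-tests, one-way ANOVA, mean ± SEM.

The thin statistical layer applied to every between-condition comparison
(cell dimensions, breadths, speeds, asymmetries).  Tests go through
scipy.stats; results carry group means and SEMs for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import StatsError

__all__ = ["GroupSample", "TestResult", "unpaired_t_test", "one_way_anova",
           "mean_sem"]


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of real-valued measurements."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not math.isfinite(v) for v in self.values):
            raise StatsError(f"group {self.label}: non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: tuple[float, ...]
    p_value: float
    group_means: tuple[float, ...]
    group_sems: tuple[float | None, ...]


def mean_sem(sample: GroupSample) -> tuple[float, float | None]:
    """Mean and standard error sd/√n (sample sd, n−1 denominator).

    SEM is undefined for a single measurement and returned as None.
    """
    if sample.n == 0:
        raise StatsError(f"group {sample.label}: empty sample")
    vals = sample.as_array()
    mean = float(vals.mean())
    if sample.n == 1:
        return mean, None
    sem = float(vals.std(ddof=1) / math.sqrt(sample.n))
    return mean, sem


def unpaired_t_test(
    a: GroupSample,
    b: GroupSample,
    variant: Literal["student", "welch"] = "student",
) -> TestResult:
    """Two-sided unpaired t-test between two groups.

    Default is Student's pooled-variance test; Welch's unequal-variance
    test is available via ``variant="welch"``.
    """
    for g in (a, b):
        if g.n < 2:
            raise StatsError(f"group {g.label}: t-test needs n >= 2, got {g.n}")
    xa, xb = a.as_array(), b.as_array()
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        if xa.mean() == xb.mean():
            # identical constants: no evidence of difference
            df = float(a.n + b.n - 2)
            return TestResult(0.0, (df,), 1.0,
                              (float(xa.mean()), float(xb.mean())),
                              (mean_sem(a)[1], mean_sem(b)[1]))
        raise StatsError("both groups have zero variance with unequal means")
    res = sps.ttest_ind(xa, xb, equal_var=(variant == "student"))
    return TestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=(float(res.df),),
        p_value=float(res.pvalue),
        group_means=(float(xa.mean()), float(xb.mean())),
        group_sems=(mean_sem(a)[1], mean_sem(b)[1]),
    )


def one_way_anova(groups: Sequence[GroupSample]) -> TestResult:
    """One-way analysis of variance across k groups.

    F statistic with (k−1, N−k) degrees of freedom; with two groups F
    equals the square of the pooled-variance t statistic.
    """
    if len(groups) < 2:
        raise StatsError(f"ANOVA needs >= 2 groups, got {len(groups)}")
    for g in groups:
        if g.n < 2:
            raise StatsError(f"group {g.label}: ANOVA needs n >= 2, got {g.n}")
    arrays = [g.as_array() for g in groups]
    k = len(arrays)
    n_total = sum(len(x) for x in arrays)
    if all(x.std(ddof=1) == 0 for x in arrays) and \
            len({float(x.mean()) for x in arrays}) == 1:
        return TestResult(0.0, (float(k - 1), float(n_total - k)), 1.0,
                          tuple(float(x.mean()) for x in arrays),
                          tuple(mean_sem(g)[1] for g in groups))
    f, p = sps.f_oneway(*arrays)
    return TestResult(
        statistic=float(f),
        degrees_of_freedom=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        group_means=tuple(float(x.mean()) for x in arrays),
        group_sems=tuple(mean_sem(g)[1] for g in groups),
    )
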