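"""Nonparametric group statistics: paired Wilcoxon signed-rank, Friedman
repeated measures, and Bonferroni-corrected post hoc pairs.

All tests are two-tailed. The Wilcoxon test drops zero differences (the
classic convention) and uses the exact tie-aware null distribution of
the positive-rank sum for n <= 25 -- so a 16-subject cohort is always on
the exact path -- and the tie-corrected normal approximation beyond. The
Friedman statistic uses average ranks with the standard tie correction
and a chi-square reference with k-1 degrees of freedom.

These are implemented in-package (rather than delegated to
``scipy.stats``) so that the exact small-n path is available with ties
and for k = 2 conditions; the scipy equivalents serve as independent
cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = ["TestResult", "wilcoxon_signed_rank", "friedman", "posthoc_pairs"]


class StatsError(ValueError):
    """Raised for invalid statistical-test inputs."""


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    method_detail: str
    adjusted_p: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p_value out of [0,1]: {self.p_value}")
        if self.adjusted_p is not None and not (self.p_value <= self.adjusted_p <= 1.0):
            raise StatsError("adjusted_p must lie in [p_value, 1]")


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-tailed p for the positive-rank sum under random signs.

    Enumerates the null distribution of W+ by dynamic programming over
    the (possibly tied, mid-)ranks, doubled so they are integers. This is
    equivalent to full enumeration of all 2^n sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2.0 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x,
    y,
    exact_n_max: int = 25,
    name: str = "wilcoxon_signed_rank",
) -> TestResult:
    """Two-tailed paired Wilcoxon signed-rank test.

    Zero differences are dropped (classic Wilcoxon convention; the count
    is reported in the note). For n <= ``exact_n_max`` non-zero pairs the
    exact tie-aware null distribution is enumerated; beyond that the
    normal approximation with tie correction is used. The statistic
    reported is W+, the positive-rank sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-D paired samples")
    d = x - y
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    note = f"{n_zero} zero differences dropped" if n_zero else ""
    if n == 0:
        warnings.warn("all paired differences are zero; degenerate Wilcoxon result", stacklevel=2)
        return TestResult(name, 0.0, 1.0, 0, "degenerate", note=note or "all differences zero")
    if n < 5:
        warnings.warn(f"only {n} non-zero differences; exact p resolution is coarse", stacklevel=2)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_n_max:
        p = _exact_signed_rank_p(w_plus, ranks)
        detail = "exact (sign enumeration, tie-aware)"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(((counts**3 - counts) / 48.0).sum())
        z = (w_plus - mu) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
        detail = "normal approximation with tie correction"
    return TestResult(name, w_plus, p, n, detail, note=note)


def friedman(data) -> TestResult:
    """Friedman repeated-measures test on a subjects x conditions matrix.

    Ranks each subject's row (average ranks on ties) and forms the
    tie-corrected chi-square statistic with df = k - 1. Requires >= 2
    conditions, >= 2 subjects and no missing cells (no imputation).
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2:
        raise StatsError("data must be a 2-D subjects x conditions matrix")
    n, k = a.shape
    if n < 2 or k < 2:
        raise StatsError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    if not np.isfinite(a).all():
        raise StatsError("missing cells are not allowed (no imputation)")
    r = np.apply_along_axis(rankdata, 1, a)
    col_sums = r.sum(axis=0)
    # Conover's tie-robust form; reduces to the classic 12/(nk(k+1)) formula
    # when every row is a full permutation of 1..k.
    a1 = float((r**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    s = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    if a1 - c1 <= 0:  # every row fully tied
        return TestResult("friedman", 0.0, 1.0, n, f"chi-square df={k - 1}", note="all rows fully tied")
    stat = (k - 1) * s / (a1 - c1)
    p = float(chi2.sf(stat, df=k - 1))
    return TestResult("friedman", float(stat), p, n, f"chi-square df={k - 1}, average-rank ties")


def posthoc_pairs(data, correction: str = "bonferroni") -> list[TestResult]:
    """Pairwise Wilcoxon tests over all condition pairs of a Friedman design.

    Bonferroni adjustment multiplies each raw p by m = k(k-1)/2 (the
    whole post hoc family of one Friedman test), capped at 1.
    """
    if correction != "bonferroni":
        raise StatsError(f"unsupported correction {correction!r}")
    a = np.asarray(data, dtype=float)
    if a.ndim != 2:
        raise StatsError("data must be a 2-D subjects x conditions matrix")
    k = a.shape[1]
    m = k * (k - 1) // 2
    out: list[TestResult] = []
    for i, j in itertools.combinations(range(k), 2):
        res = wilcoxon_signed_rank(a[:, i], a[:, j], name=f"wilcoxon[{i + 1} vs {j + 1}]")
        res.adjusted_p = min(1.0, res.p_value * m)
        out.append(res)
    return out
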