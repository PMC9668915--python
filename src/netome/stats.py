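"""Classical hypothesis tests implemented from first principles.

One-way ANOVA, the Mann-Whitney U test and Spearman rank correlation are
written out explicitly (sums of squares, rank algebra, exact small-sample
enumeration) so that every number the pipeline reports is fully specified
by this module; only the distribution tail functions come from
:mod:`scipy.special`.  Exact enumeration paths are used for the small
fixtures the synthetic generator produces, with large-sample
approximations beyond the stated cut-offs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = ["TestResult", "anova_oneway", "mann_whitney", "spearman"]

# exact Mann-Whitney enumeration is used while C(n+m, n) stays below this
_MW_EXACT_MAX_SPLITS = 20_000
_SPEARMAN_EXACT_MAX_N = 7


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    name: str
    statistic: float
    pvalue: float
    group_sizes: tuple[int, ...]
    method: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not math.isnan(self.pvalue) and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")


def anova_oneway(*groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    Parameters
    ----------
    *groups
        Two or more sequences of real observations, each of length >= 2.

    Returns
    -------
    TestResult
        F statistic on (k - 1, N - k) degrees of freedom and its upper
        tail probability.  The degenerate case of zero between- *and*
        within-group variance is reported as F = 0, p = 1 with a
        ``degenerate`` flag.
    """
    if len(groups) < 2:
        raise ValueError("anova_oneway needs at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrs):
        if a.ndim != 1 or a.size < 2:
            raise ValueError(f"group {i} must have >= 2 values")
    n = np.array([a.size for a in arrs])
    total_n = int(n.sum())
    if total_n < 3:
        raise ValueError("need at least 3 observations in total")

    grand = np.concatenate(arrs).mean()
    means = np.array([a.mean() for a in arrs])
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b = len(arrs) - 1
    df_w = total_n - len(arrs)

    flags: tuple[str, ...] = ()
    if ss_within == 0.0:
        if ss_between == 0.0:
            # all observations identical: no variance to partition
            f_stat, p = 0.0, 1.0
            flags = ("degenerate",)
        else:
            f_stat, p = math.inf, 0.0
            flags = ("zero-within-variance",)
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        # upper tail of the F(df_b, df_w) distribution
        p = float(special.fdtrc(df_b, df_w, f_stat))
    return TestResult(
        name="one-way ANOVA",
        statistic=f_stat,
        pvalue=p,
        group_sizes=tuple(int(x) for x in n),
        method=f"F({df_b}, {df_w})",
        flags=flags,
    )


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x: pairs with x > y count 1, ties count 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x, y, two_sided: bool = True) -> TestResult:
    """Mann-Whitney U test (rank-sum test) for two independent samples.

    The p-value is exact — full enumeration of the ``C(n + m, n)``
    assignments of the pooled observations to the two groups — whenever
    that enumeration is small enough; otherwise the normal approximation
    with tie correction is used.  The method actually applied is recorded
    on the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney requires non-empty samples")
    n, m = x.size, y.size
    u_obs = _mw_u(x, y)

    if math.comb(n + m, n) <= _MW_EXACT_MAX_SPLITS:
        pooled = np.concatenate([x, y])
        idx = range(n + m)
        u_values = []
        for comb in itertools.combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u_values.append(_mw_u(pooled[mask], pooled[~mask]))
        u_values = np.array(u_values)
        p_le = float(np.mean(u_values <= u_obs))
        p_ge = float(np.mean(u_values >= u_obs))
        if two_sided:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        else:
            p = p_ge
        method = "exact enumeration"
    else:
        mu = n * m / 2.0
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        nm = n + m
        sigma2 = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
        if sigma2 <= 0:
            # every pooled value identical
            return TestResult(
                "Mann-Whitney U", u_obs, 1.0, (n, m),
                method="degenerate (all tied)", flags=("degenerate",),
            )
        z = (u_obs - mu) / math.sqrt(sigma2)
        if two_sided:
            p = float(special.ndtr(-abs(z)) * 2.0)
        else:
            p = float(special.ndtr(-z))
        p = min(1.0, p)
        method = "normal approximation with tie correction"
    return TestResult("Mann-Whitney U", u_obs, p, (n, m), method=method)


def _midranks(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="stable")
    ranks = np.empty(a.size, dtype=float)
    sorted_a = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-rank tie handling.

    For n <= 7 the p-value is exact (enumeration of all n! orderings of
    one variable); for larger n the usual t approximation on
    ``rho * sqrt((n - 2) / (1 - rho^2))`` is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires equal-length vectors, n >= 3")
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            "Spearman rho", math.nan, math.nan, (n,),
            method="undefined (constant input)", flags=("constant-input",),
        )
    rx, ry = _midranks(x), _midranks(y)

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    if n <= _SPEARMAN_EXACT_MAX_N:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rho(rx, ry[list(perm)])) >= target:
                hits += 1
        p = hits / total
        method = "exact enumeration"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * special.stdtr(n - 2, -abs(t)))
        method = "t approximation"
    return TestResult("Spearman rho", rho, p, (n,), method=method)
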