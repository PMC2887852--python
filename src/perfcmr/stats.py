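"""Exact nonparametric paired and two-sample tests.

Within-patient comparisons (native vs. graft territory) use the Wilcoxon
signed-rank test; between-group comparisons use the Mann-Whitney U test.
Both are provided with an exact small-sample branch — full enumeration of the
sign-assignment / group-labelling null — and a large-sample normal
approximation with tie and continuity correction (delegated to scipy).  The
exact branch handles ties in the data, which tabulated null distributions do
not.

Two-sided p-values are ``min(1, 2 * min(P(T <= t), P(T >= t)))`` under the
enumerated null, the standard doubled-tail convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedTestError

__all__ = ["TestResult", "wilcoxon_signed_rank", "mann_whitney_u"]

#: exact enumeration limits; above them the normal approximation is used
WILCOXON_EXACT_MAX_N = 15
MWU_EXACT_MAX_TOTAL = 12

_EPS = 1e-12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n: int
    exact: bool


def _doubled_tail(null: np.ndarray, observed: float) -> float:
    scale = max(1.0, float(np.max(np.abs(null))))
    tol = _EPS * scale
    lo = float(np.mean(null <= observed + tol))
    hi = float(np.mean(null >= observed - tol))
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    exact_max_n: int = WILCOXON_EXACT_MAX_N,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    ``x`` may be the differences directly, or paired with ``y``.  Zero
    differences are dropped before ranking (Wilcoxon's original treatment);
    ties among the absolute differences receive average ranks.  With at most
    ``exact_max_n`` nonzero differences the p-value is exact, from
    enumeration of all ``2**n`` sign assignments of the observed ranks;
    otherwise the normal approximation with tie and continuity correction is
    used.  The statistic is W+, the rank sum of the positive differences.

    Raises :class:`UndefinedTestError` when fewer than 3 nonzero differences
    remain.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        yv = np.asarray(y, dtype=float)
        if yv.shape != d.shape:
            raise ValueError("paired samples must have equal length")
        d = d - yv
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    if n < 3:
        raise UndefinedTestError(
            f"only {n} nonzero difference(s); need at least 3"
        )
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        null = signs @ ranks
        p = _doubled_tail(null, w_pos)
        return TestResult(statistic=w_pos, pvalue=p, n=n, exact=True)
    p = float(
        sps.wilcoxon(
            d, zero_method="wilcox", correction=True, alternative="two-sided",
            method="approx",
        ).pvalue
    )
    return TestResult(statistic=w_pos, pvalue=p, n=n, exact=False)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample ``a``: pairs where a > b, plus half of the ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_total: int = MWU_EXACT_MAX_TOTAL,
) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    With a combined sample size of at most ``exact_max_total`` the p-value is
    exact, from enumeration of every assignment of the pooled values to the
    two group labels (ties handled by the half-count U convention); larger
    samples use the normal approximation with tie and continuity correction.
    The statistic is U of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedTestError("both groups must be non-empty")
    if len(a) < 3 or len(b) < 3:
        raise UndefinedTestError("need at least 3 observations per group")
    u_obs = _u_statistic(a, b)
    n_tot = len(a) + len(b)
    if n_tot <= exact_max_total:
        pooled = np.concatenate([a, b])
        idx = np.arange(n_tot)
        null = np.array(
            [
                _u_statistic(pooled[list(pick)], pooled[np.setdiff1d(idx, pick)])
                for pick in combinations(idx, len(a))
            ]
        )
        p = _doubled_tail(null, u_obs)
        return TestResult(statistic=u_obs, pvalue=p, n=n_tot, exact=True)
    p = float(
        sps.mannwhitneyu(
            a, b, use_continuity=True, alternative="two-sided", method="asymptotic"
        ).pvalue
    )
    return TestResult(statistic=u_obs, pvalue=p, n=n_tot, exact=False)
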