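"""Exactness and symmetry tests for the nonparametric tests.

The exact branches are checked against independent oracles: a pure-Python
enumeration (handles ties) and scipy's exact method (tie-free data only).
"""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps

from perfcmr.errors import UndefinedTestError
from perfcmr.stats import mann_whitney_u, wilcoxon_signed_rank


def wilcoxon_enumeration_oracle(d):
    """Doubled-tail exact p by looping over every sign assignment."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    lo = hi = 0
    total = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def mwu_enumeration_oracle(a, b):
    """Doubled-tail exact p by looping over every group labelling."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def u_stat(x, y):
        diff = x[:, None] - y[None, :]
        return np.sum(diff > 0) + 0.5 * np.sum(diff == 0)

    u_obs = u_stat(a, b)
    pooled = np.concatenate([a, b])
    idx = set(range(len(pooled)))
    lo = hi = total = 0
    for pick in combinations(range(len(pooled)), len(a)):
        rest = sorted(idx - set(pick))
        u = u_stat(pooled[list(pick)], pooled[rest])
        lo += u <= u_obs + 1e-9
        hi += u >= u_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


class TestWilcoxon:
    def test_three_positive_differences(self):
        # W+ = 6; only the all-positive and all-negative assignments are as
        # extreme, so the doubled-tail exact p is 2/8
        assert wilcoxon_signed_rank([1, 2, 3]).pvalue == pytest.approx(0.25)

    def test_all_zero_differences_undefined(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank(x, x)

    def test_too_few_nonzero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank([0.0, 0.0, 0.0, 1.5])

    def test_global_sign_flip_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, size=int(rng.integers(4, 12)))
            d = d[d != 0]
            if len(d) < 3:
                continue
            assert wilcoxon_signed_rank(d).pvalue == pytest.approx(
                wilcoxon_signed_rank(-d).pvalue
            )

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_matches_enumeration_with_ties(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            d = rng.integers(-3, 4, size=n).astype(float)
            d = d[d != 0]
            if len(d) < 3:
                continue
            got = wilcoxon_signed_rank(d)
            assert got.exact
            assert got.pvalue == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    @pytest.mark.parametrize("n", range(4, 11))
    def test_exact_matches_scipy_on_tie_free_data(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            d = rng.normal(0.5, 1.0, size=n)
            want = sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_signed_rank(d).pvalue == pytest.approx(want, abs=1e-10)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.4, 1.0, size=40)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        want = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert res.pvalue == pytest.approx(want)


class TestMannWhitney:
    def test_complete_separation(self):
        # U = 0; 2 of the 20 labellings are as extreme
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]).pvalue == pytest.approx(0.1)

    def test_identical_groups_p_near_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.pvalue == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.normal(0, 1, size=int(rng.integers(3, 8)))
            b = rng.normal(0.5, 1, size=int(rng.integers(3, 8)))
            assert mann_whitney_u(a, b).pvalue == pytest.approx(
                mann_whitney_u(b, a).pvalue
            )

    def test_empty_or_tiny_group_rejected(self):
        with pytest.raises(UndefinedTestError):
            mann_whitney_u([], [1, 2, 3])
        with pytest.raises(UndefinedTestError):
            mann_whitney_u([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("na,nb", [(3, 3), (3, 5), (4, 4), (5, 6), (6, 6)])
    def test_exact_matches_enumeration_with_ties(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(15):
            a = rng.integers(0, 5, size=na).astype(float)
            b = rng.integers(0, 5, size=nb).astype(float)
            got = mann_whitney_u(a, b)
            assert got.exact
            assert got.pvalue == pytest.approx(mwu_enumeration_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("na,nb", [(3, 4), (4, 5), (5, 5), (6, 6)])
    def test_exact_matches_scipy_on_tie_free_data(self, na, nb):
        rng = np.random.default_rng(na * 100 + nb)
        for _ in range(10):
            a = rng.normal(0, 1, size=na)
            b = rng.normal(0.8, 1, size=nb)
            want = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert mann_whitney_u(a, b).pvalue == pytest.approx(want, abs=1e-10)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        res = mann_whitney_u(a, b)
        assert not res.exact
        want = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=True).pvalue
        assert res.pvalue == pytest.approx(want)
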