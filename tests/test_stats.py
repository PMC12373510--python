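"""Statistics: exact paths vs brute-force enumeration, BH, Grubbs, ΔΔCt."""

import math
from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import elsquant as e


# ---------------------------------------------------------------------------
# Independent brute-force oracles (pair-counting / sign-pattern definitions,
# a different route than the rank-sum implementations under test)
# ---------------------------------------------------------------------------

def _u_pair_count(x, y):
    return sum(
        1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y
    )


def oracle_mann_whitney_p(x, y):
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = _u_pair_count(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(_u_pair_count(xs, ys))
    us = np.array(us)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))


def oracle_wilcoxon_p(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = ss.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    return float(np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-9))


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = e.mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.exact

    def test_identical_samples_give_p_one(self):
        r = e.mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            e.mann_whitney([], [1.0])

    def test_exact_path_matches_enumeration_exhaustively(self, rng):
        """For every n1 + n2 <= 8, the exact p equals the brute-force
        permutation oracle (with and without ties)."""
        for n1 in range(1, 8):
            for n2 in range(1, 9 - n1):
                for trial in range(4):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    if trial % 2:  # force ties
                        x = np.round(x)
                        y = np.round(y)
                    assert e.mann_whitney(x, y).p_value == pytest.approx(
                        oracle_mann_whitney_p(x, y), abs=1e-12
                    )

    def test_exact_path_matches_scipy_without_ties(self, rng):
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            sp = ss.mannwhitneyu(x, y, method="exact").pvalue
            assert e.mann_whitney(x, y).p_value == pytest.approx(sp, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1, size=25)
        mine = e.mann_whitney(x, y)
        assert not mine.exact
        sp = ss.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert mine.p_value == pytest.approx(sp, rel=1e-6)


class TestWilcoxon:
    def test_all_positive_differences(self):
        r = e.wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert r.p_value == pytest.approx(2 * (1 / 2**6))
        assert r.exact

    def test_degenerate_pairs_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="zero"):
            r = e.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.p_value == 1.0

    def test_exact_path_matches_enumeration(self, rng):
        for n in (5, 8, 10):
            for _ in range(5):
                x = rng.normal(size=n)
                y = x + rng.normal(0.3, 1, size=n)
                assert e.wilcoxon_signed_rank(x, y).p_value == pytest.approx(
                    oracle_wilcoxon_p(x, y), abs=1e-12
                )

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0.2, 1, size=40)
        mine = e.wilcoxon_signed_rank(x, y)
        assert not mine.exact
        sp = ss.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert mine.p_value == pytest.approx(sp, rel=1e-6)


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        df = pd.DataFrame(
            {"up": [1, 2, 3, 4, 5], "up2": [2, 4, 9, 16, 30], "down": [5, 3, 2, 1, 0]}
        )
        res = e.spearman_matrix(df)
        assert res.r.loc["up", "up2"] == pytest.approx(1.0)
        assert res.r.loc["up", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(res.r), 1.0)
        assert np.allclose(res.r.values, res.r.values.T)

    def test_r_matches_scipy(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = e.spearman_matrix(df)
        for i, j in combinations(range(4), 2):
            r_sp = ss.spearmanr(df.iloc[:, i], df.iloc[:, j]).statistic
            assert res.r.iloc[i, j] == pytest.approx(r_sp, abs=1e-12)

    def test_constant_variable_missing_and_excluded(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=10), "b": rng.normal(size=10), "c": np.ones(10)}
        )
        res = e.spearman_matrix(df)
        assert math.isnan(res.r.loc["a", "c"])
        assert math.isnan(res.p_adj.loc["a", "c"])
        # the a-b pair forms a family of size 1: adjusted == raw
        assert res.p_adj.loc["a", "b"] == pytest.approx(res.p_raw.loc["a", "b"])

    def test_adjusted_never_below_raw_and_order_preserved(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 5)))
        res = e.spearman_matrix(df)
        iu = np.triu_indices(5, 1)
        raw = res.p_raw.values[iu]
        adj = res.p_adj.values[iu]
        assert np.all(adj >= raw - 1e-15)
        assert np.all(np.diff(adj[np.argsort(raw)]) >= -1e-15)


class TestBenjaminiHochberg:
    def test_hand_worked_case(self):
        assert np.allclose(
            e.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        assert np.allclose(
            e.benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=17)
        perm = rng.permutation(17)
        adj = e.benjamini_hochberg(p)
        adj_perm = e.benjamini_hochberg(p[perm])
        assert np.allclose(adj[perm], adj_perm)


class TestGrubbs:
    def test_flags_planted_outlier(self):
        values = [10, 10.5, 9.5, 10.2, 9.8, 30]
        assert e.grubbs(values, alpha=0.05) == [5]
        g = max(abs(np.array(values) - np.mean(values))) / np.std(values, ddof=1)
        assert g > e.grubbs_critical(6, 0.05)

    def test_symmetric_triplet_clean(self):
        assert e.grubbs([1, 2, 3]) == []

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            e.grubbs([1, 2])

    def test_statistic_analytic_bound_n4(self, rng):
        """For n=4 the Grubbs statistic can never exceed (n-1)/sqrt(n)."""
        bound = 3 / math.sqrt(4)
        for _ in range(200):
            x = rng.normal(size=4) * rng.uniform(0.1, 10)
            sd = np.std(x, ddof=1)
            if sd == 0:
                continue
            g = max(abs(x - x.mean())) / sd
            assert g <= bound + 1e-12

    def test_iterative_mode_removes_multiple(self):
        values = [10, 10.1, 9.9, 10.05, 9.95, 10.02, 25, 40]
        single = e.grubbs(values, iterate=False)
        multi = e.grubbs(values, iterate=True)
        assert len(single) == 1
        assert set(single) <= set(multi)
        assert set(multi) == {6, 7}


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((20, 18, 22, 20), 1.0),
            ((25, 20, 24, 20), 0.5),
            ((22, 20, 24, 20), 4.0),
        ],
    )
    def test_worked_cases(self, args, expected):
        assert e.ddct_fold_change(*args) == pytest.approx(expected)

    def test_duplicate_wells_averaged_on_ct_scale(self):
        assert e.ddct_fold_change([25.2, 24.8], [20.1, 19.9], 24, 20) == (
            pytest.approx(0.5)
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            e.ddct_fold_change(float("nan"), 20, 24, 20)


class TestStars:
    def test_thresholds(self):
        assert e.significance_stars(0.2) == "ns"
        assert e.significance_stars(0.04) == "*"
        assert e.significance_stars(0.009) == "**"
        assert e.significance_stars(0.0009) == "***"
        assert e.significance_stars(1e-5) == "****"
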