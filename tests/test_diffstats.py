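"""Differential statistics: worked values, oracle equivalence, degenerate cases."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sepsig.diffstats import (bh_fdr, fold_change, mann_whitney, one_way_anova,
                              pca_scores, probe_stats_table, t_test)
from sepsig.matrix import ExpressionMatrix
import pandas as pd


class TestFoldChange:
    @pytest.mark.parametrize("a, b, expected", [
        ([5.0, 5.0], [0.0, 0.0], 32.0),
        ([0.0, 0.0], [2.0, 2.0], -4.0),
        ([1.0, 3.0], [2.0, 2.0], 1.0),
    ])
    def test_worked_values(self, a, b, expected):
        assert fold_change(a, b) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=6),
           st.lists(st.floats(-10, 10), min_size=1, max_size=6))
    def test_antisymmetry_and_magnitude(self, a, b):
        fc = fold_change(a, b)
        rev = fold_change(b, a)
        assert abs(fc) >= 1.0
        if abs(fc) > 1.0 + 1e-12:
            assert rev == pytest.approx(-fc, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])


class TestTTest:
    def test_identical_samples(self):
        t, p = t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_pooled_hand_value(self):
        # mean diff -3, pooled sd 1, se = sqrt(2/3) -> t = -3.674
        t, _ = t_test([1, 2, 3], [4, 5, 6], welch=False)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(0)
        low = 0
        for _ in range(20):
            a = rng.normal(0, 1, 30)
            b = rng.normal(3, 1, 30)
            low += t_test(a, b)[1] < 1e-6
        assert low >= 19


class TestAnova:
    def test_hand_sums_of_squares(self):
        # SSB=16, SSW=1.5 -> F = (16/2)/(1.5/3) = 16.0
        f, p = one_way_anova([[1, 2], [3, 4], [5, 6]])
        assert f == pytest.approx(16.0)
        assert 0 < p < 1

    def test_agrees_with_scipy_on_generic_data(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.0)]
        f, p = one_way_anova(groups)
        f2, p2 = sps.f_oneway(*groups)
        assert f == pytest.approx(float(f2)) and p == pytest.approx(float(p2))

    def test_degenerate_conventions(self):
        assert one_way_anova([[1, 1], [1, 1]]) == (0.0, 1.0)
        f, p = one_way_anova([[1, 1], [2, 2]])
        assert np.isinf(f) and p == 0.0

    def test_null_f_is_moderate(self):
        rng = np.random.default_rng(2)
        fs = [one_way_anova([rng.normal(0, 1, 10) for _ in range(4)])[0]
              for _ in range(50)]
        assert max(fs) < 10.0


def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.002, 0.01, 0.03, 0.04]),
                                   [0.008, 0.02, 0.04, 0.04])

    def test_single_and_saturated(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_bruteforce_and_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        q = bh_fdr(p)
        np.testing.assert_allclose(q, _bh_bruteforce(p), atol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1.0).all()


def _mw_enumeration_p(a, b):
    """Exact two-sided p by symmetry of the null U distribution."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    total = n_a * len(b)
    stat_obs = min(u_obs, total - u_obs)
    count = 0
    combos = list(itertools.combinations(range(len(pooled)), n_a))
    for combo in combos:
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        if min(u, total - u) <= stat_obs + 1e-9:
            count += 1
    return count / len(combos)


class TestMannWhitney:
    def test_exact_small_sample_worked_value(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 6.0)

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 6))
            vals = rng.permutation(20)[: n_a + n_b].astype(float)
            a, b = vals[:n_a], vals[n_a:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(_mw_enumeration_p(a, b), abs=1e-12)

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(5.0, 0.5, 40)   # CRP-like sepsis shift
        b = rng.lognormal(3.0, 0.5, 40)
        assert mann_whitney(a, b)[1] < 1e-3


class TestPca:
    def test_rank_one_matrix(self):
        v = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 0.5, 2.0])
        m = ExpressionMatrix(pd.DataFrame(v, index=list("abc"),
                                          columns=list("wxyz")))
        scores = pca_scores(m, 1)
        assert scores.shape == (4, 1)
        with pytest.raises(ValueError):
            pca_scores(m, 2)  # rank 1 only

    def test_separated_clusters_split_on_pc1(self):
        rng = np.random.default_rng(5)
        grp = np.array([0] * 10 + [1] * 10)
        vals = rng.normal(0, 0.3, (20, 20)) + np.where(grp, 5.0, 0.0)[:, None]
        m = ExpressionMatrix(pd.DataFrame(vals.T,
                                          index=[f"p{i}" for i in range(20)],
                                          columns=[f"s{i}" for i in range(20)]))
        pc1 = pca_scores(m, 1)["PC1"].to_numpy()
        lo, hi = pc1[grp == 0], pc1[grp == 1]
        assert (hi.min() > lo.max()) or (lo.min() > hi.max())

    def test_total_variance_conserved(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (8, 6))
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"p{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(6)]))
        k = 5
        scores = pca_scores(m, k)
        centred = vals.T - vals.T.mean(axis=0)
        assert scores.to_numpy().var(axis=0, ddof=1).sum() == pytest.approx(
            centred.var(axis=0, ddof=1).sum())

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, (10, 8))
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"p{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)]))
        s1 = pca_scores(m, 3)
        s2 = pca_scores(m, 3)
        pd.testing.assert_frame_equal(s1, s2)


def test_probe_stats_table_recovers_planted_direction(small_cohort):
    mat, ann = small_cohort
    tab = probe_stats_table(mat, ann, ("SIRS", "ABDM", "PLMN"), ("CNTRL",),
                            timepoint="D1")
    assert tab.loc["UPGENE", "fc"] > 8
    assert tab.loc["UPGENE", "q"] < 0.01
    assert tab["q"].ge(tab["p"] - 1e-15).all()
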