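"""Rank tests, Friedman, Holm-Bonferroni, Yates chi-squared vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bottlechoice.stats import (
    chi_squared_yates,
    family_report,
    friedman,
    holm_bonferroni,
    mann_whitney,
    wilcoxon_signed_rank,
)


def _enumeration_p(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    stat_obs = min(u_obs, n1 * len(y) - u_obs)
    stats = [
        min(u_of(idx), n1 * len(y) - u_of(idx))
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    return np.mean([s <= stat_obs for s in stats])


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.1)  # 2/20 label assignments as extreme

    def test_identical_samples_give_p_one(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 5))
        y = rng.normal(loc=0.8, size=rng.integers(3, 5))
        r = mann_whitney(x, y)
        assert r.method == "exact"
        assert r.p == pytest.approx(_enumeration_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_large_sample_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=30)
        y = rng.normal(loc=0.4, size=35)
        r = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxonSignedRank:
    def test_paired_alias(self):
        r = mann_whitney([1, 2, 3, 4, 6], [2, 3, 5, 6, 9], paired=True)
        assert r.name == "wilcoxon_signed_rank"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.5, 1.0, size=10)
        r = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_all_zero_differences(self):
        r = wilcoxon_signed_rank(np.zeros(5))
        assert r.p == 1.0


class TestFriedman:
    def test_constant_matrix_is_null(self):
        r = friedman(np.ones((6, 4)))
        assert r.statistic == 0.0 and r.p == 1.0

    def test_identical_rankings_maximal_statistic(self):
        m = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (8, 1))
        r = friedman(m)
        assert r.df == 3
        # maximal chi-squared for n=8, k=4 is n*(k-1) = 24
        assert r.statistic == pytest.approx(24.0)
        assert r.p < 0.001

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(10, 3))
        r = friedman(m)
        ref = sps.friedmanchisquare(*[m[:, j] for j in range(3)])
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            friedman(m)


class TestHolmBonferroni:
    def test_hand_worked_example(self):
        # sorted (0.01, 0.03, 0.04) * (3, 2, 1) = (0.03, 0.06, 0.04),
        # monotone-corrected to (0.03, 0.06, 0.06), mapped back
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.2]), [0.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_properties(self, ps):
        adj = holm_bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # smallest adjusted p equals the Bonferroni bound of the smallest raw p
        assert adj.min() == pytest.approx(min(1.0, len(ps) * min(ps)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, ps, rnd):
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adj = holm_bonferroni(ps)
        adj_perm = holm_bonferroni([ps[i] for i in perm])
        np.testing.assert_allclose(adj_perm, [adj[i] for i in perm])


def _yates_direct(table):
    """Independent closed-form evaluation of the floored Yates statistic."""
    t = np.asarray(table, float)
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    d = np.maximum(np.abs(t - e) - 0.5, 0.0)
    return float((d**2 / e).sum())


class TestChiSquaredYates:
    def test_avoider_proportion_table(self):
        # 17/35 avoiders in one group vs 0/13 in the other
        r = chi_squared_yates([[17, 18], [0, 13]])
        assert r.statistic == pytest.approx(7.77, abs=0.01)
        assert r.p == pytest.approx(0.0053, abs=3e-4)

    def test_balanced_table_is_null(self):
        r = chi_squared_yates([[5, 5], [5, 5]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_symmetry_under_table_rearrangement(self):
        t = np.array([[12, 7], [3, 9]])
        base = chi_squared_yates(t).statistic
        assert chi_squared_yates(t.T).statistic == pytest.approx(base)
        assert chi_squared_yates(t[::-1]).statistic == pytest.approx(base)
        assert chi_squared_yates(t[:, ::-1]).statistic == pytest.approx(base)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_formula_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=(2, 2))
        r = chi_squared_yates(t)
        assert r.statistic == pytest.approx(_yates_direct(t), abs=1e-12)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        if np.all(np.abs(t - expected) > 0.5):  # scipy does not floor the correction
            ref = sps.chi2_contingency(t, correction=True)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_squared_yates([[0, 0], [3, 4]])


class TestFamilyReport:
    def test_within_family_adjustment(self):
        df = pd.DataFrame(
            {
                "family": ["f1"] * 4 + ["f2"],
                "label": list("abcde"),
                "p": [0.01, 0.02, 0.04, 0.30, 0.04],
            }
        )
        out = family_report(df)
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()
        # a singleton family is unadjusted
        assert out.loc[out["family"] == "f2", "p_adjusted"].iloc[0] == pytest.approx(0.04)
        assert out.loc[0, "p_adjusted"] == pytest.approx(0.04)  # 0.01 * 4

    def test_empty_input(self):
        out = family_report(pd.DataFrame(columns=["family", "p"]))
        assert len(out) == 0 and "p_adjusted" in out.columns
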