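"""Unit and oracle tests for the statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import gammaln

from epimark.stats import (
    ContingencyTable,
    bh_adjust,
    chi_square,
    fisher_exact_2x2,
    fisher_exact_rxc,
    kruskal_wallis,
    spearman,
    wilcoxon_rank_sum,
)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.01, 0.04, 0.03, 0.005], [0.02, 0.04, 0.04, 0.02]),
        ],
    )
    def test_step_up_by_hand(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)


class TestFisher2x2:
    def test_msi_hypermutation_table(self):
        """The MSI-by-hypermutation count table gives the analytic
        210 / 818,809,200 ~ 2.565e-7 (printed as 2.6e-07)."""
        p = fisher_exact_2x2([[19, 2], [0, 12]])
        assert p == pytest.approx(210 / 818_809_200, rel=1e-9)
        assert f"{p:.1e}" == "2.6e-07"

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_zero_margin(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        """Brute-force sum over the hypergeometric support equals the
        implementation on random small tables."""
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 8, size=(2, 2))
        if t.sum() == 0 or min(t.sum(0).min(), t.sum(1).min()) == 0:
            return
        r1, r2 = t.sum(axis=1)
        c1 = t[:, 0].sum()
        n = t.sum()
        probs = {
            a: sps.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, c1 - r2), min(c1, r1) + 1)
        }
        obs = probs[t[0, 0]]
        expected = sum(v for v in probs.values() if v <= obs * (1 + 1e-7))
        assert fisher_exact_2x2(t) == pytest.approx(min(1.0, expected), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = rng.integers(1, 12, size=(2, 2))
        assert fisher_exact_2x2(t) == pytest.approx(
            sps.fisher_exact(t)[1], rel=1e-6
        )

    def test_invariance_under_transpose_and_swaps(self):
        t = np.array([[5, 2], [1, 9]])
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t.T) == pytest.approx(p)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
        assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)


class TestFisherRxC:
    def test_histology_hypermutation_table(self):
        """The 3x2 hypermutated-by-histology counts give ~0.34 (exact
        enumeration value 0.346642..., to 7 digits the value R's
        fisher.test reports)."""
        p = fisher_exact_rxc([[10, 11], [5, 2], [4, 1]])
        assert p == pytest.approx(0.3466424, abs=1e-6)
        assert abs(p - 0.34) < 0.01

    def test_2x2_consistency(self):
        t = [[6, 3], [2, 8]]
        assert fisher_exact_rxc(t) == pytest.approx(fisher_exact_2x2(t), abs=1e-12)

    def test_zero_column_collapses(self):
        """An all-zero column carries no mass: the result equals the
        reduced table's."""
        assert fisher_exact_rxc([[4, 0, 2], [1, 0, 6]]) == pytest.approx(
            fisher_exact_2x2([[4, 2], [1, 6]]), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_random_3x2_reduces_to_probability_mass_sum(self, seed):
        """Independent check: enumerate every table with the observed
        margins directly and sum the no-more-probable masses."""
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 6, size=(3, 2))
        t[0, 0] += 1  # avoid all-zero margins
        row, col = t.sum(1), t.sum(0)
        n = t.sum()
        const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

        def logp(tab):
            return const - gammaln(np.asarray(tab) + 1).sum()

        obs = logp(t)
        total = 0.0
        for a in range(row[0] + 1):
            for b in range(row[1] + 1):
                c00, c10 = a, b
                c20 = col[0] - a - b
                if not 0 <= c20 <= row[2]:
                    continue
                cand = [[c00, row[0] - c00], [c10, row[1] - c10], [c20, row[2] - c20]]
                if min(min(r) for r in cand) < 0:
                    continue
                lp = logp(cand)
                if lp <= obs + math.log1p(1e-7):
                    total += math.exp(lp)
        assert fisher_exact_rxc(t) == pytest.approx(min(1.0, total), rel=1e-9)

    def test_enumeration_limit(self):
        big = [[100, 100], [100, 100]]
        with pytest.raises(ValueError, match="enumeration limit"):
            fisher_exact_rxc(big)
        p_mc = fisher_exact_rxc(big, monte_carlo=True, n_draws=2000, seed=0)
        assert 0.5 < p_mc <= 1.0


class TestChiSquare:
    def test_fap_vs_ls_dmp_direction_table(self):
        """Hypo/hyper DMP counts in FAP adenomas vs LS low-grade
        adenomas: Yates-corrected p prints as 0.008."""
        stat, df, p = chi_square([[917, 78], [24022, 2826]])
        assert df == 1
        assert f"{p:.3f}" == "0.008"

    def test_table_at_expectation(self):
        stat, df, p = chi_square([[10, 20], [20, 40]], yates=False)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_with_correction(self):
        t = [[30, 10], [20, 25]]
        stat, df, p = chi_square(t)
        s_stat, s_p, s_df, _ = sps.chi2_contingency(t, correction=True)
        assert stat == pytest.approx(s_stat)
        assert p == pytest.approx(s_p)

    def test_agrees_with_fisher_on_large_counts(self):
        t = [[300, 260], [250, 310]]
        _, _, p_chi = chi_square(t)
        p_f = fisher_exact_2x2(t)
        assert 0.001 < p_f < 0.5
        assert abs(p_chi - p_f) / p_f < 0.2

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [1, 2]])


class TestWilcoxon:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 3.0, 4.0] * 2
        assert wilcoxon_rank_sum(x, x) == 1.0

    def test_fully_separated_small(self):
        """x={1,2} vs y={3,4}: 2 of C(4,2)=6 assignments are as
        extreme on either side -> two-sided 1/3."""
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        ranks = sps.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:6].sum()
        lo = hi = 0
        total = 0
        for combo in itertools.combinations(range(12), 6):
            w = ranks[list(combo)].sum()
            total += 1
            lo += w <= w_obs + 1e-9
            hi += w >= w_obs - 1e-9
        expected = min(1.0, 2 * min(lo, hi) / total)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(expected)

    def test_approximation_close_to_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.7, 1, 30)
        p = wilcoxon_rank_sum(x, y)
        p_scipy = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(p_scipy, rel=0.05)


class TestKruskalWallis:
    def test_fully_separated_three_groups(self):
        """Groups occupying ranks 1-5, 6-10, 11-15 give H = 12.5."""
        h, df, p = kruskal_wallis([[1, 2, 3, 4, 5], [6, 7, 8, 9, 10], [11, 12, 13, 14, 15]])
        assert h == pytest.approx(12.5)
        assert df == 2
        assert p < 0.01

    def test_two_groups_equals_rank_sum_z_squared(self):
        """For two groups without ties, H equals the square of the
        (uncorrected) rank-sum z statistic."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=10)
        h, _, _ = kruskal_wallis([x, y])
        ranks = sps.rankdata(np.concatenate([x, y]))
        n, nx, ny = 18, 8, 10
        w = ranks[:nx].sum()
        z = (w - nx * (n + 1) / 2) / math.sqrt(nx * ny * (n + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_all_tied(self):
        h, df, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0
        assert p == 1.0

    def test_matches_scipy_with_ties(self):
        groups = [[1, 2, 2, 3], [2, 4, 4, 5, 6], [1, 1, 7, 8]]
        h, _, p = kruskal_wallis(groups)
        s = sps.kruskal(*groups)
        assert h == pytest.approx(s.statistic)
        assert p == pytest.approx(s.pvalue)


class TestSpearman:
    def test_perfect_antitone(self):
        r, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        x = np.linspace(0, 1, 12)
        r, p = spearman(x, np.exp(3 * x))
        assert r == pytest.approx(1.0)

    def test_exact_permutation_matches_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, p = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)

        def pear(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a * b).sum() / math.sqrt((a**2).sum() * (b**2).sum())

        count = sum(
            abs(pear(rx, ry[list(perm)])) >= abs(r) - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert p == pytest.approx(count / 120)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p = spearman(x, y)
        s = sps.spearmanr(x, y)
        assert r == pytest.approx(s.statistic)
        assert p == pytest.approx(s.pvalue, rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, 2]]))
    with pytest.raises(ValueError):
        ContingencyTable(np.array([[1, -2], [0, 3]]))
    t = ContingencyTable(np.array([[1, 2], [3, 4]]), ["MSI", "MSS"], ["hyper", "non"])
    assert t.row_labels == ["MSI", "MSS"]
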