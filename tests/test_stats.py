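"""Classical tests, the JZS Bayes factor, and multiplicity correction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gradientspace as gs
from gradientspace.errors import DegenerateInputError, ValidationError
from gradientspace.stats import welch_t_test


class TestTTest:
    def test_identical_paired_samples_are_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            gs.t_test(x, x, "paired")
        # constant nonzero difference is equally degenerate
        with pytest.raises(DegenerateInputError):
            gs.t_test(x + 1, x, "paired")

    def test_pooled_t_matches_hand_computation(self):
        # constructed samples: n1=4 mean 10 var 4; n2=4 mean 7 var 4
        x = np.array([8.0, 9.0, 11.0, 12.0])  # mean 10, s2 = 10/3
        y = np.array([5.0, 6.0, 8.0, 9.0])  # mean 7, s2 = 10/3
        sp2 = 10 / 3
        expected_t = 3.0 / np.sqrt(sp2 * 0.5)
        t, df, p = gs.t_test(x, y, "independent")
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert df == 6
        assert p == pytest.approx(2 * sps.t.sf(expected_t, 6), rel=1e-12)

    def test_paired_matches_scipy(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        t, df, p = gs.t_test(x, y, "paired")
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_welch_available(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 5, 40)
        t, df, p = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestJzsBayesFactor:
    def test_null_t_favors_h0(self):
        assert gs.jzs_bf10(0.0, 26) < 1

    def test_monotone_in_abs_t(self):
        bfs = [gs.jzs_bf10(t, 26) for t in np.linspace(0, 6, 13)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_limits_in_t(self):
        assert gs.jzs_bf10(1e-9, 20) < 1
        assert gs.jzs_bf10(12.0, 20) > 1e6

    def test_symmetry_in_sign(self):
        assert gs.jzs_bf10(2.5, 18) == pytest.approx(gs.jzs_bf10(-2.5, 18), rel=1e-10)

    def test_matches_monte_carlo_marginal_likelihood(self):
        """Spot-check the quadrature against a prior-draw Monte-Carlo
        estimate of the marginal likelihood (full grid in acceptance)."""
        rng = np.random.default_rng(7)
        delta = sps.cauchy.rvs(scale=0.707, size=200_000, random_state=rng)
        for t, n in [(2.0, 23), (3.0, 12)]:
            m1 = sps.nct.pdf(t, n - 1, delta * np.sqrt(n)).mean()
            bf_mc = m1 / sps.t.pdf(t, n - 1)
            assert gs.jzs_bf10(t, n) == pytest.approx(bf_mc, rel=0.02)

    def test_posterior_summaries_are_ordered(self):
        bf, post = gs.jzs_bf10(4.331, 26, return_posterior=True)
        lo, hi = post.ci95
        assert lo < post.median < hi
        assert bf > 100

    def test_independent_design_uses_effective_n(self):
        # equal split maximizes effective n, so evidence is strongest there
        bf_even = gs.jzs_bf10(3.0, 20, 20)
        bf_skew = gs.jzs_bf10(3.0, 5, 35)
        assert bf_even > bf_skew

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            gs.jzs_bf10(np.inf, 10)
        with pytest.raises(ValidationError):
            gs.jzs_bf10(1.0, 10, rscale=0.0)


class TestRankTests:
    def test_all_positive_differences_exact_p(self):
        # n=6, all differences positive: W = 21, two-tailed p = 2/64
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x - np.array([1.0, 2.0, 1.5, 0.5, 2.5, 3.0])
        w, p = gs.rank_test(x, y, "paired")
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_identical_independent_samples_give_half_u(self, rng):
        x = rng.normal(size=8)
        u, p = gs.rank_test(x, x.copy(), "independent")
        assert u == pytest.approx(8 * 8 / 2)

    def test_paired_exact_matches_signflip_enumeration(self, rng):
        for _ in range(5):
            d = rng.normal(size=7)
            d[d == 0] = 0.1
            x = d
            y = np.zeros_like(d)
            w, p = gs.rank_test(x, y, "paired")
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            # exhaustive sign-flip null distribution of W+
            stats = [
                ranks[np.array(signs, dtype=bool)].sum()
                for signs in itertools.product([0, 1], repeat=7)
            ]
            stats = np.asarray(stats)
            mu = ranks.sum() / 2
            p_exact = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
            assert w == pytest.approx(w_obs)
            assert p == pytest.approx(p_exact, abs=1e-10)

    def test_all_zero_differences_degenerate(self):
        x = np.ones(5)
        with pytest.raises(DegenerateInputError):
            gs.rank_test(x, x, "paired")


class TestKendallTauB:
    def test_perfect_concordance_and_reversal(self):
        x = np.arange(10.0)
        assert gs.kendall_tau_b(x, x * 2 + 1)[0] == pytest.approx(1.0)
        assert gs.kendall_tau_b(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        for n in [10, 25, 50]:
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, _ = gs.kendall_tau_b(x, y)
            c = d = tx = ty = 0
            for i in range(n):
                for j in range(i + 1, n):
                    sx, sy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
                    if sx == 0 and sy == 0:
                        continue
                    if sx == 0:
                        tx += 1
                    elif sy == 0:
                        ty += 1
                    elif sx == sy:
                        c += 1
                    else:
                        d += 1
            n0 = n * (n - 1) / 2
            n1 = sum(m * (m - 1) / 2 for m in np.unique(x, return_counts=True)[1])
            n2 = sum(m * (m - 1) / 2 for m in np.unique(y, return_counts=True)[1])
            expected = (c - d) / np.sqrt((n0 - n1) * (n0 - n2))
            assert tau == pytest.approx(expected, abs=1e-12)

    def test_all_tied_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            gs.kendall_tau_b(np.ones(10), np.arange(10.0))


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(gs.bh_fdr([0.123]), [0.123])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(gs.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        # another hand case: (0.01, 0.04, 0.03) -> sorted (0.01,0.03,0.04):
        # adj = (0.03, 0.04, 0.045->0.04) -> monotone (0.03, 0.04, 0.04)
        np.testing.assert_allclose(gs.bh_fdr([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_all_ones_and_order_restored(self, rng):
        np.testing.assert_array_equal(gs.bh_fdr(np.ones(5)), np.ones(5))
        p = rng.uniform(size=20)
        adj = gs.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            gs.bh_fdr([0.5, 1.2])


class TestClassifyEvidence:
    @pytest.mark.parametrize(
        "bf, label, passes",
        [
            (136.5, "decisive", True),
            (55.2, "very strong", True),
            (15.7, "strong", True),
            (5.0, "moderate", False),
            (2.0, "anecdotal", False),
            (1.0, "no evidence", False),
            (0.2, "moderate (H0)", False),
            (0.005, "decisive (H0)", False),
        ],
    )
    def test_bins(self, bf, label, passes):
        got_label, got_passes = gs.classify_evidence(bf)
        assert got_label == label
        assert got_passes is passes

    def test_invalid(self):
        with pytest.raises(ValidationError):
            gs.classify_evidence(0.0)


class TestCompareConditions:
    def _tidy(self, rng, n=10, delta=0.0):
        rows = []
        for i in range(n):
            base = rng.normal()
            rows.append({"subject": f"S{i}", "condition": "BL", "metric": "m",
                         "networks": "", "value": base})
            rows.append({"subject": f"S{i}", "condition": "X", "metric": "m",
                         "networks": "", "value": base + delta + rng.normal(0, 0.3)})
        return pd.DataFrame(rows)

    def test_single_contrast_fdr_identity(self, rng):
        df = self._tidy(rng, delta=1.0)
        res = gs.compare_conditions(df, test="X", control="BL", design="paired")
        assert len(res) == 1
        assert res["p_fdr"].iloc[0] == pytest.approx(res["p_two_tailed"].iloc[0])
        assert res["bf10"].iloc[0] > 10
        assert res["passes_threshold"].iloc[0]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            gs.compare_conditions(pd.DataFrame({"a": [1]}), "X", "BL")
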