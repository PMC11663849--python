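"""Unit and oracle tests for the shared statistical machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epfsit.stats_core import (
    TukeyResult,
    compact_letters,
    glm_fit,
    oneway_anova,
    tukey_hsd,
)


class TestOnewayAnova:
    def test_matches_hand_decomposition_on_toy_table(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]
        # hand decomposition: SSB = Σ nᵢ(x̄ᵢ − x̄)², SSW = Σ Σ (x − x̄ᵢ)²
        flat = [v for g in groups for v in g]
        grand = sum(flat) / len(flat)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
        f_hand = (ssb / 2) / (ssw / 6)
        res = oneway_anova(groups)
        assert res.df_between == 2
        assert res.df_within == 6
        assert res.f == pytest.approx(f_hand, abs=1e-10)
        assert res.p == pytest.approx(stats.f.sf(f_hand, 2, 6), abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 9)
        res = oneway_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert res.f == pytest.approx(t**2, rel=1e-12)

    def test_shifting_one_group_increases_f(self, rng):
        a, b, c = (rng.normal(0, 1, 6) for _ in range(3))
        f0 = oneway_anova([a, b, c]).f
        f1 = oneway_anova([a, b, c + 5.0]).f
        assert f1 > f0

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            oneway_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            oneway_anova([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        res = tukey_hsd({"a": a, "b": b})
        (_, _, diff, q, p_adj) = res.pairs[0]
        tt = stats.ttest_ind(a, b, equal_var=True)
        # studentized range with k=2: q = |t|·√2 and the same p-value
        assert q == pytest.approx(abs(tt.statistic) * math.sqrt(2), rel=1e-10)
        assert p_adj == pytest.approx(tt.pvalue, abs=1e-6)

    def test_identical_groups_never_rejected(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = tukey_hsd({"a": g, "b": g, "c": g})
        assert all(p == 1.0 for *_, p in res.pairs)

    def test_matches_statsmodels_pairwise(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = {
            "g1": rng.normal(0, 1, 6),
            "g2": rng.normal(1.5, 1, 6),
            "g3": rng.normal(0.5, 1, 6),
        }
        res = tukey_hsd(data)
        values = np.concatenate(list(data.values()))
        labels = np.repeat(list(data), [len(v) for v in data.values()])
        sm_res = pairwise_tukeyhsd(values, labels)
        ours = {frozenset((a, b)): p for a, b, _, _, p in res.pairs}
        for (g1, g2), p in zip(
            itertools.combinations(data, 2), sm_res.pvalues
        ):
            assert ours[frozenset((g1, g2))] == pytest.approx(p, abs=1e-6)


def _tukey_from_pvalues(pvals: dict) -> TukeyResult:
    pairs = tuple((a, b, 0.0, 0.0, p) for (a, b), p in pvals.items())
    return TukeyResult(pairs=pairs)


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        res = _tukey_from_pvalues({("A", "B"): 0.9, ("A", "C"): 0.8, ("B", "C"): 0.7})
        assert set(compact_letters(res, 0.05).values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        res = _tukey_from_pvalues({("A", "B"): 0.01, ("A", "C"): 0.01, ("B", "C"): 0.01})
        letters = compact_letters(res, 0.05)
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_chain_pattern(self):
        # A differs from C; B bridges both
        res = _tukey_from_pvalues({("A", "B"): 0.5, ("A", "C"): 0.01, ("B", "C"): 0.5})
        letters = compact_letters(res, 0.05)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    @pytest.mark.parametrize("n_groups,seed", [(3, 0), (4, 1), (5, 2), (6, 3), (5, 4)])
    def test_defining_invariant_exhaustive(self, n_groups, seed):
        """Shared letter <=> non-significant pair, for random p patterns."""
        rng = np.random.default_rng(seed)
        names = [f"G{i}" for i in range(n_groups)]
        pvals = {
            (a, b): float(rng.choice([0.001, 0.5]))
            for a, b in itertools.combinations(names, 2)
        }
        letters = compact_letters(_tukey_from_pvalues(pvals), alpha=0.05)
        for (a, b), p in pvals.items():
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (p >= 0.05), (a, b, p, letters)


class TestGlmFit:
    def test_poisson_intercept_is_log_mean(self):
        y = [3, 5, 2, 7, 4]
        fit = glm_fit(y, [[1.0]] * 5, family="poisson-log")
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(math.log(np.mean(y)), abs=1e-8)

    def test_balanced_binomial_logit_intercept_zero(self):
        fit = glm_fit([50.0], [[1.0]], family="binomial-logit", trials=[100.0])
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_grid_maximiser(self):
        days = np.array([1.0, 2.0, 3.0, 4.0])
        deaths = np.array([1.0, 3.0, 6.0, 9.0])
        trials = np.full(4, 10.0)
        X = np.column_stack([np.ones(4), days])
        fit = glm_fit(deaths, X, family="binomial-logit", trials=trials)

        def negll(b0, b1):
            p = 1 / (1 + np.exp(-(b0 + b1 * days)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(deaths * np.log(p) + (trials - deaths) * np.log(1 - p))

        # iteratively refined grid search, independent of IRLS
        b0_lo, b0_hi, b1_lo, b1_hi = -10.0, 10.0, -5.0, 5.0
        for _ in range(8):
            b0s = np.linspace(b0_lo, b0_hi, 41)
            b1s = np.linspace(b1_lo, b1_hi, 41)
            vals = np.array([[negll(b0, b1) for b1 in b1s] for b0 in b0s])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            db0, db1 = b0s[1] - b0s[0], b1s[1] - b1s[0]
            b0_lo, b0_hi = b0s[i] - db0, b0s[i] + db0
            b1_lo, b1_hi = b1s[j] - db1, b1s[j] + db1
        assert fit.coefficients[0] == pytest.approx((b0_lo + b0_hi) / 2, abs=1e-4)
        assert fit.coefficients[1] == pytest.approx((b1_lo + b1_hi) / 2, abs=1e-4)

    @pytest.mark.parametrize("family", ["binomial-logit", "binomial-probit", "poisson-log"])
    def test_matches_statsmodels(self, family, rng):
        import statsmodels.api as sm

        x = np.linspace(-1, 1, 12)
        X = np.column_stack([np.ones(12), x])
        if family.startswith("binomial"):
            trials = np.full(12, 25.0)
            p = stats.norm.cdf(0.3 + 0.8 * x)
            y = rng.binomial(25, p).astype(float)
            link = sm.families.links.Logit() if family.endswith("logit") else sm.families.links.Probit()
            sm_fit = sm.GLM(
                np.column_stack([y, trials - y]), X, family=sm.families.Binomial(link)
            ).fit()
            fit = glm_fit(y, X, family=family, trials=trials)
        else:
            mu = np.exp(1.0 + 0.5 * x)
            y = rng.poisson(mu).astype(float)
            sm_fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            fit = glm_fit(y, X, family=family)
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.covariance)), sm_fit.bse, rtol=1e-4
        )

    def test_deviance_trace_non_increasing(self, rng):
        x = np.linspace(-2, 2, 20)
        X = np.column_stack([np.ones(20), x])
        y = rng.binomial(10, 1 / (1 + np.exp(-2 * x))).astype(float)
        fit = glm_fit(y, X, family="binomial-logit", trials=np.full(20, 10.0))
        trace = np.array(fit.deviance_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_separation_flagged(self):
        # perfectly separated step data
        days = np.array([1.0, 2.0, 3.0, 4.0])
        deaths = np.array([0.0, 0.0, 10.0, 10.0])
        X = np.column_stack([np.ones(4), days])
        fit = glm_fit(deaths, X, family="binomial-logit", trials=np.full(4, 10.0))
        assert not fit.converged
        assert fit.message

    def test_rank_deficient_design_reported(self):
        X = [[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]
        fit = glm_fit([1.0, 2.0, 3.0], X, family="poisson-log")
        assert not fit.converged
        assert "rank" in fit.message

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_logit_fit_reproduces_generating_probabilities_sign(self, seed):
        """Slope sign of the fit agrees with the generating slope."""
        r = np.random.default_rng(seed)
        x = np.linspace(0, 1, 10)
        X = np.column_stack([np.ones(10), x])
        y = r.binomial(50, 1 / (1 + np.exp(-(0.5 + 3.0 * x)))).astype(float)
        fit = glm_fit(y, X, family="binomial-logit", trials=np.full(10, 50.0))
        if fit.converged:
            assert fit.coefficients[1] > 0
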